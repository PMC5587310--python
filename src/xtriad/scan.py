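"""Chromosome-wide sliding-window scan with FDR control.

Each window of 1-4 contiguous SNPs is analyzed as a haplotype unit; windows
overlap with step 1.  Every window contributes one likelihood-ratio p-value
(all relative risks free vs all equal to 1), and the p-values of one scan are
converted to q-values by the Benjamini-Hochberg step-up rule; a window is
declared significant at q <= 0.1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoDataError, WindowUninformativeError
from .fitcore import fit_window
from .xmodel import PenetranceSpec, Window

DEFAULT_FDR_THRESHOLD = 0.1


@dataclass
class ScanTable:
    """Ordered per-window scan results (one row per window x model)."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def make_windows(n_markers: int, length: int) -> list[Window]:
    """All contiguous windows of exactly ``length`` markers, step 1."""
    if not 1 <= length <= 4:
        raise ValueError("window length must be in 1..4")
    if length > n_markers:
        raise ValueError(
            f"window length {length} exceeds number of markers {n_markers}"
        )
    return [
        Window(start_index=s, length=length, marker_ids=("?",) * length)
        for s in range(n_markers - length + 1)
    ]


def _windows_for_map(marker_map, length: int) -> list[Window]:
    n = marker_map.n_markers
    if length > n:
        raise ValueError(f"window length {length} exceeds number of markers {n}")
    return [
        Window(
            start_index=s,
            length=length,
            marker_ids=tuple(marker_map.marker_ids[s : s + length]),
        )
        for s in range(n - length + 1)
    ]


def compute_qvalues(p, method: str = "bh", pi0_lambda: float = 0.5) -> np.ndarray:
    """FDR q-values for a vector of p-values.

    The default is the Benjamini-Hochberg step-up rule: after sorting the m
    p-values ascending, ``q_(i) = min_{j >= i} p_(j) * m / j``, mapped back to
    the input order and clipped to 1.  ``method="storey"`` additionally scales
    by an estimate of the null proportion pi0.  NaN entries (failed windows)
    are ignored in m and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    obs = ~np.isnan(p)
    if np.any((p[obs] < 0) | (p[obs] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pv = p[obs]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    if method == "storey":
        pi0 = min(1.0, float(np.mean(pv > pi0_lambda)) / (1.0 - pi0_lambda))
        qv = np.minimum(qv * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    out = np.empty(m)
    out[order] = qv
    q[obs] = out
    return q


def run_scan(
    data,
    length: int = 1,
    spec: PenetranceSpec | None = None,
    min_freq: float = 0.01,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    qvalue_method: str = "bh",
    compute_ci: bool = True,
) -> ScanTable:
    """Slide a fixed-length window across the map and fit every position.

    Windows that fail (uninformative after pruning, or no usable families)
    are recorded with missing p- and q-values and excluded from the BH
    denominator.  The scan is deterministic given its input.
    """
    spec = spec or PenetranceSpec()
    windows = _windows_for_map(data.map, length)
    rows = []
    n_ok = 0
    for win in windows:
        base = {
            "window_start": win.start_index,
            "window_length": win.length,
            "snp_ids": list(win.marker_ids),
            "positions_bp": data.map.positions_bp[
                win.start_index : win.stop_index
            ].tolist(),
            "model": spec.model,
        }
        try:
            fit = fit_window(data, win, spec, min_freq=min_freq,
                             compute_ci=compute_ci)
        except (WindowUninformativeError, NoDataError) as exc:
            rows.append({**base, "p_value": np.nan, "failure": str(exc)})
            continue
        n_ok += 1
        rows.append({
            **base,
            "haplotypes": list(fit.haplotype_table.haplotypes),
            "reference_haplotype": fit.haplotype_table.haplotypes[
                fit.reference_index
            ],
            "frequencies": fit.haplotype_table.frequencies.tolist(),
            "rr_single_dose": fit.rr_single_dose.tolist(),
            "rr_single_ci_low": fit.rr_single_ci[:, 0].tolist(),
            "rr_single_ci_high": fit.rr_single_ci[:, 1].tolist(),
            "rr_double_dose": fit.rr_double_dose.tolist(),
            "rr_boys": None if fit.rr_boys is None else fit.rr_boys.tolist(),
            "loglik_full": fit.loglik_full,
            "loglik_null": fit.loglik_null,
            "lrt_statistic": fit.lrt_statistic,
            "df": fit.df,
            "p_value": fit.p_value,
            "n_families_used": fit.n_families_used,
            "n_mendelian_inconsistent": fit.n_mendelian_inconsistent,
            "pruned_haplotypes": fit.pruned_haplotypes,
            "converged": fit.converged,
            "failure": "",
        })
    if n_ok == 0:
        raise NoDataError("no window could be fitted")

    df = pd.DataFrame(rows)
    df["q_value"] = compute_qvalues(df["p_value"].to_numpy(), method=qvalue_method)
    df["significant"] = df["q_value"] <= fdr_threshold
    metadata = {
        "model": spec.model,
        "window_length": length,
        "min_hap_freq": min_freq,
        "fdr_threshold": fdr_threshold,
        "qvalue_method": qvalue_method,
        "n_windows": len(windows),
        "n_windows_failed": len(windows) - n_ok,
        "n_triads": data.n_triads,
    }
    return ScanTable(table=df, metadata=metadata)


def plot_manhattan(scan_table: ScanTable, path,
                   fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> None:
    """Plain Manhattan-style scatter: window position vs -log10 p.

    A horizontal line marks the largest p-value still significant at the
    q-value threshold (omitted when nothing is significant).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scan_table.table.dropna(subset=["p_value"])
    pos = df["positions_bp"].map(lambda v: v[0]).to_numpy(dtype=float)
    logp = -np.log10(np.clip(df["p_value"].to_numpy(dtype=float), 1e-300, None))
    fig, ax = plt.subplots(figsize=(9, 3.5))
    ax.scatter(pos / 1e6, logp, s=8, color="#30506e")
    sig = df[df["q_value"] <= fdr_threshold]
    if not sig.empty:
        ax.axhline(
            -np.log10(sig["p_value"].max()), color="firebrick",
            linestyle="--", linewidth=1,
            label=f"FDR {fdr_threshold:g}",
        )
        ax.legend(frameon=False)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"{scan_table.metadata.get('model', '')} "
                 f"(window length {scan_table.metadata.get('window_length', '?')})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
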