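"""Group-level summaries, hypothesis tests and bootstrap error bars.

Mirrors the comparison structure of the source experiment: per-subset (and
per-side) summaries of windowed MFI, normalised peak counts, peak
intensities and fold amplitudes; rank-sum / t / ANOVA comparisons with
Bonferroni-adjusted post-hoc pairs; and bootstrap errors for pulse-period
frequency distributions, with error bars equal to twice the bootstrap SD.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pulse import bin_periods
from .qc import Exclusion

logger = logging.getLogger(__name__)

__all__ = [
    "GROUP_METRICS",
    "CompareResult",
    "summarize_by_group",
    "compare_groups",
    "bootstrap_period_frequencies",
    "write_report",
]

GROUP_METRICS = (
    "mean_mfi_3_12",
    "peaks_per_10_frames",
    "max_peak_mfi",
    "max_fold_amplitude",
)


def _parse_periods(value) -> list[float]:
    if isinstance(value, (list, tuple, np.ndarray)):
        return [float(v) for v in value]
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return []
    return [float(tok) for tok in str(value).split(";") if tok]


def summarize_by_group(
    profiles: pd.DataFrame, by: Sequence[str] = ("subset",)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-cell profiles into group summaries.

    Returns ``(summary, period_fractions)``: the summary holds cell counts
    and mean/SD/SEM of each metric in :data:`GROUP_METRICS`; the fraction
    table gives, per group, the fraction of pulse periods in each 1-h bin,
    computed over cells showing at least two peaks (fractions per group sum
    to 1).  Aggregation is deterministic and invariant to input row order.
    """
    by = list(by)
    unknown = [k for k in by if k not in profiles.columns]
    if unknown:
        raise KeyError(f"unknown grouping keys {unknown}")
    df = profiles.sort_values("cell_id").reset_index(drop=True)
    rows = []
    for keys, grp in df.groupby(by, dropna=False, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(by, keys))
        row["n_cells"] = len(grp)
        for metric in GROUP_METRICS:
            vals = grp[metric].astype(float).dropna()
            row[f"{metric}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{metric}_sem"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        rows.append(row)
    summary = pd.DataFrame(rows)

    frac_rows = []
    pooled = df[df["n_peaks"] >= 2]
    max_bin = 1
    parsed = {}
    for keys, grp in pooled.groupby(by, dropna=False, sort=True):
        periods = [p for v in grp["periods_h"] for p in _parse_periods(v)]
        parsed[keys if isinstance(keys, tuple) else (keys,)] = (len(grp), periods)
        if periods:
            max_bin = max(max_bin, int(bin_periods(periods).index.max()))
    for keys, (n_cells, periods) in parsed.items():
        counts = bin_periods(periods, max_bin=max_bin)
        total = counts.sum()
        row = dict(zip(by, keys))
        row["n_cells"] = n_cells
        for h in counts.index:
            row[f"frac_{h}h"] = counts.loc[h] / total if total else np.nan
        frac_rows.append(row)
    period_fractions = pd.DataFrame(frac_rows)
    n_empty = summary["n_cells"].eq(0).sum() if len(summary) else 0
    if n_empty:
        logger.info("omitted %d empty groups from summary", n_empty)
    return summary, period_fractions


@dataclass
class CompareResult:
    """Result of a group comparison."""

    method: str
    metric: str
    overall_statistic: float
    overall_pvalue: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_bonf


def compare_groups(
    profiles: pd.DataFrame,
    metric: str,
    group_col: str = "subset",
    method: str = "rank_sum",
    groups: Optional[Sequence[str]] = None,
) -> CompareResult:
    """Compare a per-cell metric between groups.

    ``method``: ``rank_sum`` (Mann–Whitney U, midranks on ties), ``t``
    (two-sample t test) or ``anova_bonferroni`` (one-way ANOVA with
    pairwise t post-tests).  All pairwise p-values are Bonferroni-adjusted
    (multiplied by the number of post-hoc pairs, capped at 1).  Each group
    needs at least two observations; fewer is an explicit error.
    """
    if method not in ("rank_sum", "t", "anova_bonferroni"):
        raise ValueError(f"unknown method {method!r}")
    if metric not in profiles.columns:
        raise KeyError(f"unknown metric {metric!r}")
    if group_col not in profiles.columns:
        raise KeyError(f"unknown grouping key {group_col!r}")
    labels = list(groups) if groups is not None else sorted(
        profiles[group_col].dropna().unique()
    )
    if len(labels) < 2:
        raise ValueError("need at least 2 groups to compare")
    samples = {}
    for lab in labels:
        vals = (
            profiles.loc[profiles[group_col] == lab, metric]
            .astype(float)
            .dropna()
            .to_numpy()
        )
        if len(vals) < 2:
            raise ValueError(
                f"group {lab!r} has {len(vals)} observations; need >= 2"
            )
        samples[lab] = vals

    pairs = list(combinations(labels, 2))
    k = len(pairs)
    rows = []
    for a, b in pairs:
        if method == "rank_sum":
            res = sps.mannwhitneyu(samples[a], samples[b], alternative="two-sided")
        else:
            res = sps.ttest_ind(samples[a], samples[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_bonf": min(float(res.pvalue) * k, 1.0),
            }
        )
    pairwise = pd.DataFrame(rows)
    if method == "anova_bonferroni":
        f = sps.f_oneway(*samples.values())
        overall_stat, overall_p = float(f.statistic), float(f.pvalue)
    elif len(labels) == 2:
        overall_stat, overall_p = (
            float(pairwise["statistic"].iloc[0]),
            float(pairwise["p_raw"].iloc[0]),
        )
    else:
        kw = sps.kruskal(*samples.values()) if method == "rank_sum" else sps.f_oneway(*samples.values())
        overall_stat, overall_p = float(kw.statistic), float(kw.pvalue)
    return CompareResult(
        method=method,
        metric=metric,
        overall_statistic=overall_stat,
        overall_pvalue=overall_p,
        pairwise=pairwise,
    )


def bootstrap_period_frequencies(
    periods_by_cell: Mapping[str, Sequence[float]],
    n_boot: int = 2000,
    seed: int = 0,
    method: str = "cells",
) -> pd.DataFrame:
    """Bootstrap errors for the pulse-period frequency distribution.

    Cells contributing at least one period (i.e. at least two peaks) are
    resampled with replacement ``n_boot`` times; per 1-h bin the SD of the
    resampled frequency is reported, with error bar = 2 x SD.
    Deterministic under a fixed seed.

    ``method="cells"`` is the primary nonparametric cell-level resampling;
    ``method="residuals"`` resamples per-cell residuals around the mean
    per-cell frequency vector instead.  The result's ``attrs["method"]``
    records which was used.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    eligible = {
        str(cid): np.asarray(list(p), dtype=float)
        for cid, p in periods_by_cell.items()
        if len(list(p)) > 0
    }
    if not eligible:
        raise ValueError("no cells with >= 2 peaks; cannot bootstrap frequencies")
    cells = sorted(eligible)
    all_periods = np.concatenate([eligible[c] for c in cells])
    point = bin_periods(all_periods)
    bins = point.index.to_numpy()
    # per-cell bin count matrix
    C = np.zeros((len(cells), len(bins)))
    for r, c in enumerate(cells):
        counts = bin_periods(eligible[c], max_bin=int(bins.max()))
        C[r] = counts.reindex(bins, fill_value=0).to_numpy()
    totals = C.sum(axis=1)
    rng = np.random.default_rng(seed)
    n = len(cells)
    if method == "cells":
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_counts = C[idx].sum(axis=1)  # (n_boot, n_bins)
        boot_freq = boot_counts / boot_counts.sum(axis=1, keepdims=True)
    elif method == "residuals":
        F = C / totals[:, None]  # per-cell frequency vectors
        fbar = F.mean(axis=0)
        resid = F - fbar
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_freq = fbar + resid[idx].mean(axis=1)
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")
    sd = boot_freq.std(axis=0, ddof=1)
    out = pd.DataFrame(
        {
            "period_h": bins,
            "frequency": point.to_numpy() / point.sum(),
            "boot_sd": sd,
            "error_bar": 2.0 * sd,
        }
    )
    out.attrs["method"] = method
    out.attrs["n_boot"] = n_boot
    out.attrs["n_cells"] = n
    return out


def write_report(
    outdir: str | Path,
    profiles: Optional[pd.DataFrame] = None,
    summary: Optional[pd.DataFrame] = None,
    period_fractions: Optional[pd.DataFrame] = None,
    period_frequencies: Optional[pd.DataFrame] = None,
    exclusions: Optional[Sequence[Exclusion]] = None,
    metadata: Optional[Mapping] = None,
    traces=None,
    plots: bool = False,
) -> list[Path]:
    """Write CSV tables, JSON run metadata and optional figures.

    Reruns with identical inputs produce byte-identical CSVs.  The
    metadata JSON records package/library versions, the QC exclusion
    ledger counts and any caller-supplied configuration (e.g. seeds and
    thresholds).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    if profiles is not None:
        _write(profiles, "profiles.csv")
    if summary is not None:
        _write(summary, "group_summary.csv")
    if period_fractions is not None:
        _write(period_fractions, "period_fractions.csv")
    if period_frequencies is not None:
        _write(period_frequencies, "period_frequencies.csv")
    exclusion_counts: dict[str, int] = {}
    if exclusions is not None:
        rows = [{"cell_id": e.trace.cell_id, "reason": e.reason} for e in exclusions]
        _write(pd.DataFrame(rows, columns=["cell_id", "reason"]), "exclusions.csv")
        for e in exclusions:
            exclusion_counts[e.reason] = exclusion_counts.get(e.reason, 0) + 1

    import pulsetrace

    meta = {
        "pulsetrace_version": pulsetrace.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_profiles": int(len(profiles)) if profiles is not None else 0,
        "exclusion_counts": exclusion_counts,
    }
    if period_frequencies is not None and period_frequencies.attrs:
        meta["bootstrap"] = {
            k: period_frequencies.attrs[k] for k in sorted(period_frequencies.attrs)
        }
    if metadata:
        meta.update(metadata)
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    written.append(meta_path)

    if plots:
        written.extend(_write_plots(outdir, traces, profiles, period_frequencies))
    return written


def _write_plots(outdir: Path, traces, profiles, period_frequencies) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if traces:
        n = min(len(traces), 25)
        ncols = int(np.ceil(np.sqrt(n)))
        nrows = int(np.ceil(n / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2 * nrows), squeeze=False)
        for ax, tr in zip(axes.flat, traces[:n]):
            ax.plot(tr.times_h, tr.mfi, lw=0.8)
            ax.set_title(tr.cell_id, fontsize=7)
        for ax in axes.flat[n:]:
            ax.axis("off")
        fig.supxlabel("time (h)")
        fig.supylabel("MFI (a.u.)")
        fig.tight_layout()
        p = outdir / "traces.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    if period_frequencies is not None:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(
            period_frequencies["period_h"],
            period_frequencies["frequency"],
            yerr=period_frequencies["error_bar"],
            capsize=3,
        )
        ax.set_xlabel("pulse period (h)")
        ax.set_ylabel("frequency")
        fig.tight_layout()
        p = outdir / "period_histogram.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
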