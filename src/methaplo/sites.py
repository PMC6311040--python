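"""Binomial calling of 5mC / 5hmC-modified CpG sites and co-modified sites.

A site with ``n_c`` modified and ``n_t`` unmodified read calls is tested
against the null that every "C" readout is a conversion error occurring
at a known per-base rate: p = P(X >= n_c) for X ~ Binomial(n_c + n_t,
error_rate).  P-values are Benjamini–Hochberg corrected per channel per
tissue; a site is called modified when q <= alpha and coverage >= min_cov.
A CpG called modified in both the oxBS (5mC) and TAB (5hmC) channels is a
co-modified site — evidence that distinct cell subpopulations carry the
two marks on the same cytosine position.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_COV = 5


def binomial_pvalue(n_c: int, n_t: int, error_rate: float) -> float:
    """Upper-tail binomial p-value P(X >= n_c), X ~ Bin(n_c + n_t, error_rate)."""
    if n_c < 0 or n_t < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 < error_rate < 1.0:
        raise ValueError(f"error_rate must lie in (0, 1), got {error_rate}")
    return float(stats.binom.sf(n_c - 1, n_c + n_t, error_rate))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_modified_sites(
    counts: pd.DataFrame,
    error_rate: float,
    alpha: float = DEFAULT_ALPHA,
    min_cov: int = DEFAULT_MIN_COV,
    channel: str = "5mC",
) -> pd.DataFrame:
    """Call modified sites from a chrom/pos/n_c/n_t count table.

    Modification level n_c/(n_c+n_t), p and q are reported for every site;
    ``called`` additionally requires q <= alpha and coverage >= min_cov.
    """
    required = {"chrom", "pos", "n_c", "n_t"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    out = counts.copy()
    if out.empty:
        for col in ("coverage", "level", "p_value", "q_value", "called"):
            out[col] = []
        out["channel"] = channel
        return out
    n_c = out["n_c"].to_numpy(dtype=np.int64)
    n_t = out["n_t"].to_numpy(dtype=np.int64)
    cov = n_c + n_t
    if not 0.0 < error_rate < 1.0:
        raise ValueError(f"error_rate must lie in (0, 1), got {error_rate}")
    out["coverage"] = cov
    with np.errstate(invalid="ignore"):
        out["level"] = np.where(cov > 0, n_c / np.maximum(cov, 1), np.nan)
    out["p_value"] = stats.binom.sf(n_c - 1, cov, error_rate)
    out["q_value"] = bh_adjust(out["p_value"])
    out["called"] = (out["q_value"] <= alpha) & (cov >= min_cov)
    out["channel"] = channel
    return out


def co_modified_sites(mc_calls: pd.DataFrame, hmc_calls: pd.DataFrame) -> set[tuple[str, int]]:
    """CpGs called modified in both channels: {(chrom, pos), ...}."""
    called = []
    for df in (mc_calls, hmc_calls):
        sub = df.loc[df["called"], ["chrom", "pos"]]
        called.append(set(zip(sub["chrom"], sub["pos"])))
    return called[0] & called[1]


def estimate_conversion_error(
    spike_counts: pd.DataFrame, true_state: str = "unmodified"
) -> float:
    """Pooled conversion-error rate from spike-in control counts.

    ``spike_counts`` holds chrom/pos/n_c/n_t rows over spike-in cytosines
    whose true state is known (e.g. an unmodified lambda-DNA control, for
    which every "C" readout is a conversion failure).  Rows from several
    spike contigs pool naturally — the estimate is coverage-weighted:
    sum(misreads) / sum(total).  With zero observed misreads the rate is
    floored at 1/(total + 1) so the binomial null stays well-defined.
    """
    if true_state not in ("unmodified", "modified"):
        raise ValueError("true_state must be 'unmodified' or 'modified'")
    n_c = int(spike_counts["n_c"].sum())
    n_t = int(spike_counts["n_t"].sum())
    total = n_c + n_t
    if total == 0:
        raise ValueError("spike-in control has zero total coverage")
    misread = n_c if true_state == "unmodified" else n_t
    if misread == 0:
        return 1.0 / (total + 1)
    return misread / total
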