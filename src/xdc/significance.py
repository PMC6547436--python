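"""Significance tests: per-genome chi-square, the cross-genome bootstrap
partition test for new vs old proteins, and the ratio-ratio correlation.

The chi-square is a two-cell goodness-of-fit with 1 df on genome-level
pooled counts: aligned vs non-aligned junctions against their expected
split. The bootstrap repartitions each genome's proteins into pseudo-new /
pseudo-old sets of the original sizes and asks how often at least as many
genomes as observed show a larger pseudo-new ratio.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .models import AlignmentCounts, BootstrapResult, GenomeSummary

logger = logging.getLogger(__name__)

# cap on floats held per bootstrap chunk, to bound memory
_CHUNK_BUDGET = 4_000_000


def chi_square_obs_exp(
    observed: float, expected: float, n_boundaries: float
) -> tuple[float, float]:
    """Two-cell goodness-of-fit: (O-E)^2/E + (O-E)^2/(N-E), chi2(1) tail."""
    if not 0 < expected < n_boundaries:
        raise ValueError(
            f"expected count {expected} outside (0, {n_boundaries}): "
            "chi-square undefined"
        )
    if observed > n_boundaries:
        raise ValueError("observed exceeds the number of boundaries")
    diff = observed - expected
    chi2 = diff * diff / expected + diff * diff / (n_boundaries - expected)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def summarize_genome(
    genome_id: str,
    counts: AlignmentCounts,
    alpha: float = 0.01,
    subset: str = "all",
    taxon_group: str = "",
) -> GenomeSummary:
    """Wrap genome-scope counts with ratio and chi-square significance.

    Degenerate cases (expected 0 or equal to the boundary count) are
    flagged with NaN statistics and ``significant=False``.
    """
    try:
        chi2, p = chi_square_obs_exp(
            counts.observed, counts.expected, counts.n_boundaries
        )
    except ValueError:
        logger.warning("genome %s (%s): chi-square undefined", genome_id, counts.cls)
        chi2, p = math.nan, math.nan
    return GenomeSummary(
        genome_id=genome_id,
        cls=counts.cls,
        counts=counts,
        ratio=counts.ratio,
        chi2=chi2,
        p_value=p,
        significant=bool(p < alpha) if not math.isnan(p) else False,
        subset=subset,
        taxon_group=taxon_group,
    )


def bootstrap_new_old(
    genome_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_trials: int = 50_000,
    seed: int | None = None,
    add_one: bool = False,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Cross-genome bootstrap partition test.

    ``genome_data`` maps genome id to per-protein arrays
    ``(observed, expected, is_new)`` over that genome's eligible proteins.
    Each trial repartitions every genome's proteins uniformly at random
    into pseudo-new/pseudo-old sets of the original sizes; the trial count
    is the number of genomes whose pseudo-new observed/expected ratio
    strictly exceeds the pseudo-old one (ties count as not greater).
    p = #(trial count >= actual count) / n_trials, with an optional
    add-one correction.
    """
    if rng is None:
        rng = np.random.default_rng(seed)

    usable: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    actual_count = 0
    for gid, (obs, exp, is_new) in genome_data.items():
        obs = np.asarray(obs, dtype=float)
        exp = np.asarray(exp, dtype=float)
        is_new = np.asarray(is_new, dtype=bool)
        k = int(is_new.sum())
        if k == 0 or k == is_new.size:
            logger.warning(
                "genome %s excluded from bootstrap: needs >=1 new and >=1 "
                "old protein (n_new=%d of %d)",
                gid,
                k,
                is_new.size,
            )
            continue
        new_ratio = obs[is_new].sum() / exp[is_new].sum()
        old_ratio = obs[~is_new].sum() / exp[~is_new].sum()
        if new_ratio > old_ratio:
            actual_count += 1
        usable[gid] = (obs, exp, k)
    if not usable:
        raise ValueError("no genome has both new and old proteins")

    trial_counts = np.zeros(n_trials, dtype=np.int64)
    for obs, exp, k in usable.values():
        n = obs.size
        o_tot, e_tot = obs.sum(), exp.sum()
        chunk = max(1, min(n_trials, _CHUNK_BUDGET // n))
        start = 0
        while start < n_trials:
            m = min(chunk, n_trials - start)
            u = rng.random((m, n))
            sel = np.argpartition(u, k, axis=1)[:, :k]
            so = obs[sel].sum(axis=1)
            se = exp[sel].sum(axis=1)
            greater = so / se > (o_tot - so) / (e_tot - se)
            trial_counts[start : start + m] += greater
            start += m

    extreme = int((trial_counts >= actual_count).sum())
    if add_one:
        p = (extreme + 1) / (n_trials + 1)
    else:
        p = extreme / n_trials
    return BootstrapResult(
        n_trials=n_trials,
        n_genomes=len(usable),
        actual_count=actual_count,
        p_value=p,
        trial_count_mean=float(trial_counts.mean()),
        trial_count_std=float(trial_counts.std()),
        trial_counts=trial_counts,
    )


def pearson_ratio_correlation(x, y) -> tuple[float, float]:
    """Pearson R and two-sided p for paired per-genome ratios."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("ratio vectors must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 genomes for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
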