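"""Scoring normalization strategies by GGM-pathway overlap and age association.

The primary score classifies every unordered glycan pair into a 2x2 table —
edge in both the inferred GGM and the reference pathway (true positive),
GGM only (false positive), pathway only (false negative), neither (true
negative) — and summarizes it with a one-sided Fisher exact (hypergeometric
tail) p-value: the lower the p, the stronger the enrichment of pathway
steps among inferred edges.  Each strategy's score is bootstrapped over
samples (resample -> renormalize -> re-infer), and strategies are ranked
by the median bootstrap p-value.

A secondary evaluation ranks strategies by the fraction of glycans whose
normalized abundance is significantly associated with age (OLS slope,
BH-FDR within dataset), averaged across cohorts with the multi-platform
weighting described in :func:`weighted_average_fractions`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import GlycomicsDataset
from .glycan_model import ReferencePathway
from .network import infer_ggm
from .normalize import NormalizationSpec, apply_strategy

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapTable",
    "StrategyEvaluation",
    "AgeAssociationResult",
    "contingency_counts",
    "fisher_overlap_pvalue",
    "bootstrap_evaluate",
    "rank_strategies",
    "age_fraction",
    "weighted_average_fractions",
]


@dataclass(frozen=True)
class OverlapTable:
    """2x2 classification of all unordered glycan pairs."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total_pairs(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class StrategyEvaluation:
    """Bootstrap summary of one strategy's overlap score."""

    label: str
    pvalues: np.ndarray
    median_p: float
    ci_low: float
    ci_high: float
    n_skipped: int = 0
    rank: int | None = None


@dataclass
class AgeAssociationResult:
    """Per-glycan age regression results and the significant fraction."""

    table: pd.DataFrame  # columns: glycan, slope, pvalue, significant
    fraction: float
    q: float


def contingency_counts(
    ggm_edges: frozenset[tuple[str, str]] | set, pathway: ReferencePathway,
    nodes: list[str] | None = None,
) -> OverlapTable:
    """Classify all unordered node pairs by GGM/pathway edge membership.

    When ``nodes`` is given it must equal the pathway's node set; in any
    case every GGM edge endpoint must be a pathway node.  The pair
    universe is all C(p, 2) unordered pairs of pathway nodes.
    """
    path_nodes = set(pathway.nodes)
    if nodes is not None:
        ggm_nodes = set(nodes)
        if ggm_nodes != path_nodes:
            diff = sorted(ggm_nodes.symmetric_difference(path_nodes))
            raise ValueError(f"GGM and pathway node sets differ: {diff}")
    e_ggm = {tuple(sorted(e)) for e in ggm_edges}
    for a, b in e_ggm:
        if a not in path_nodes or b not in path_nodes:
            raise ValueError(f"GGM edge endpoint not in pathway nodes: {(a, b)}")
    e_path = set(pathway.edge_set)
    p = len(path_nodes)
    total = p * (p - 1) // 2
    tp = len(e_ggm & e_path)
    fp = len(e_ggm - e_path)
    fn = len(e_path - e_ggm)
    tn = total - tp - fp - fn
    return OverlapTable(tp=tp, fp=fp, fn=fn, tn=tn)


def fisher_overlap_pvalue(t: OverlapTable, alternative: str = "greater") -> float:
    """Fisher exact p-value of the overlap table.

    ``greater`` (default): hypergeometric upper tail — the probability of
    drawing at least ``tp`` pathway pairs when the GGM's ``tp + fp`` edges
    are placed at random among all pairs.  Exact log-gamma arithmetic via
    the hypergeometric distribution; ``two_sided`` delegates to the exact
    two-sided Fisher test.
    """
    M = t.total_pairs
    K = t.tp + t.fn  # pathway pairs
    n = t.tp + t.fp  # GGM edges
    if alternative == "greater":
        return float(stats.hypergeom.sf(t.tp - 1, M, K, n))
    if alternative == "two_sided":
        return float(stats.fisher_exact([[t.tp, t.fp], [t.fn, t.tn]], alternative="two-sided")[1])
    raise ValueError(f"unknown alternative {alternative!r}")


def _single_pass_pvalue(
    d: GlycomicsDataset,
    spec: NormalizationSpec,
    pathway: ReferencePathway,
    q: float,
    alternative: str,
    ggm_method: str,
) -> float:
    normalized = apply_strategy(spec, d)
    ggm = infer_ggm(normalized, q=q, method=ggm_method)
    table = contingency_counts(ggm.edges, pathway, nodes=ggm.nodes)
    return fisher_overlap_pvalue(table, alternative=alternative)


def bootstrap_evaluate(
    d: GlycomicsDataset,
    spec: NormalizationSpec,
    pathway: ReferencePathway,
    B: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    q: float = 0.01,
    alternative: str = "greater",
    renormalize: bool = True,
    ggm_method: str = "null_density",
    indices: np.ndarray | None = None,
    max_skip_fraction: float = 0.05,
) -> StrategyEvaluation:
    """Bootstrap a strategy's overlap p-value over sample resamples.

    For each of ``B`` replicates, samples are drawn with replacement,
    the strategy is re-applied (so data-dependent parameters like the
    quotient reference are recomputed within the replicate unless
    ``renormalize`` is off, in which case the dataset is normalized once
    and its rows are resampled), the GGM is inferred and the overlap
    p-value computed.  Returns the median p and the 2.5/97.5 percentile
    interval.  Replicates that fail (e.g. a glycan becomes constant) are
    skipped with a warning; more than ``max_skip_fraction`` skips is an
    error.  ``indices`` (shape B x n) overrides the resampling for audit.
    """
    if np.isnan(d.values).any():
        raise ValueError("dataset contains missing values; filter before evaluating")
    if B < 1:
        raise ValueError("B must be >= 1")
    n = d.n_samples
    if indices is None:
        rng = np.random.default_rng(seed)
        indices = rng.integers(0, n, size=(B, n))
    else:
        indices = np.asarray(indices)
        if indices.shape != (B, n):
            raise ValueError(f"indices must have shape {(B, n)}, got {indices.shape}")

    base = d if renormalize else apply_strategy(spec, d)
    rep_spec = spec if renormalize else NormalizationSpec("raw")

    pvals = []
    n_skipped = 0
    for b in range(B):
        idx = indices[b]
        # positional resample; suffix ids keep the index unique
        abund = base.abundance.iloc[idx]
        abund = abund.set_axis([f"b{b}_{k}" for k in range(n)], axis=0)
        rep = GlycomicsDataset(abund, pd.DataFrame(index=abund.index),
                               base.glycan_meta, base.platform)
        try:
            pvals.append(
                _single_pass_pvalue(rep, rep_spec, pathway, q, alternative, ggm_method)
            )
        except (ValueError, RuntimeError) as err:
            n_skipped += 1
            warnings.warn(
                f"strategy {spec.label!r}: replicate {b} skipped ({err})", stacklevel=2
            )
    if n_skipped > max_skip_fraction * B:
        raise RuntimeError(
            f"strategy {spec.label!r}: {n_skipped}/{B} bootstrap replicates failed"
        )
    pvals = np.asarray(pvals)
    return StrategyEvaluation(
        label=spec.label,
        pvalues=pvals,
        median_p=float(np.median(pvals)),
        ci_low=float(np.percentile(pvals, 2.5)),
        ci_high=float(np.percentile(pvals, 97.5)),
        n_skipped=n_skipped,
    )


def rank_strategies(evaluations) -> list[StrategyEvaluation]:
    """Order strategies by ascending median p; ties broken by label (stable)."""
    if not evaluations:
        raise ValueError("no evaluations to rank")
    ordered = sorted(evaluations, key=lambda e: (e.median_p, e.label))
    return [replace(ev, rank=i + 1) for i, ev in enumerate(ordered)]


def age_fraction(d: GlycomicsDataset, q: float = 0.01) -> AgeAssociationResult:
    """Fraction of glycans significantly associated with age (BH-FDR ``q``).

    Per glycan: OLS of normalized abundance on age with a two-sided t-test
    on the slope; BH correction across the dataset's glycans.  Constant
    glycan columns have no defined test and are treated as non-significant
    with a warning.
    """
    if "age" not in d.sample_meta.columns:
        raise ValueError("sample metadata carries no 'age' column")
    age = pd.to_numeric(d.sample_meta["age"], errors="coerce")
    if age.isna().any():
        missing = age.index[age.isna()].tolist()
        raise ValueError(f"missing age for samples: {missing}")
    age = age.to_numpy(dtype=float)
    x = d.values
    if np.isnan(x).any():
        raise ValueError("dataset contains missing values")

    slopes = np.full(d.n_glycans, np.nan)
    pvalues = np.ones(d.n_glycans)
    testable = np.ones(d.n_glycans, dtype=bool)
    for j in range(d.n_glycans):
        col = x[:, j]
        if np.ptp(col) == 0:
            testable[j] = False
            warnings.warn(
                f"glycan {d.glycan_ids[j]!r} is constant; treated as non-significant",
                stacklevel=2,
            )
            continue
        res = stats.linregress(age, col)
        slopes[j] = res.slope
        pvalues[j] = res.pvalue

    significant = np.zeros(d.n_glycans, dtype=bool)
    if testable.any():
        reject, *_ = multipletests(pvalues[testable], alpha=q, method="fdr_bh")
        significant[testable] = reject
    table = pd.DataFrame(
        {
            "glycan": d.glycan_ids,
            "slope": slopes,
            "pvalue": pvalues,
            "significant": significant,
        }
    )
    fraction = float(significant.sum()) / d.n_glycans
    return AgeAssociationResult(table=table, fraction=fraction, q=q)


def weighted_average_fractions(
    fractions: dict[str, float],
    platform_groups: dict[str, str],
    primary_group: str = "lc-esi-ms",
) -> dict[str, float]:
    """Two-stage mean of significant-association fractions across cohorts.

    Cohorts of the ``primary_group`` platform (the replicated one) are
    first averaged among themselves; the overall value is then the plain
    mean of that group average together with each remaining cohort's
    fraction.  No sample-size weighting.
    """
    unknown = sorted(set(fractions) - set(platform_groups))
    if unknown:
        raise ValueError(f"no platform group for dataset(s): {unknown}")
    primary = [v for k, v in fractions.items() if platform_groups[k] == primary_group]
    others = [v for k, v in fractions.items() if platform_groups[k] != primary_group]
    if not primary:
        raise ValueError(f"no dataset in primary group {primary_group!r}")
    primary_avg = float(np.mean(primary))
    overall = float(np.mean([primary_avg] + others))
    return {"primary_average": primary_avg, "weighted_average": overall}
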