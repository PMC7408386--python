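"""Normalization strategies for glycomics abundance tables.

Seven base methods are provided — raw, per-sample median centering, total
area (closure), probabilistic quotient, total area followed by quotient,
per-glycan quantile normalization and per-glycan rank transform — each
optionally followed by a natural-log transform (median centering excepted:
centred values can be non-positive), and each optionally applied per IgG
subclass block for subclass-resolved platforms.  The full menu is 13 base
strategies, plus 10 per-subclass variants on subclass-resolved data (23).

All operations require complete-case input (no missing values) and return
a new dataset; inputs are never modified in place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import GlycomicsDataset

__all__ = [
    "NormalizationSpec",
    "total_area",
    "median_center",
    "probabilistic_quotient",
    "ta_quotient",
    "quantile_normalize",
    "rank_transform",
    "log_transform",
    "apply_per_subclass",
    "enumerate_strategies",
    "apply_strategy",
    "spec_from_label",
    "BASE_METHODS",
]

BASE_METHODS = ("raw", "quantile", "rank", "ta", "median", "quotient", "taquotient")
_SUBCLASS_ELIGIBLE = ("quantile", "rank", "ta", "quotient", "taquotient")
_LOG_ELIGIBLE = ("raw", "quantile", "rank", "ta", "quotient", "taquotient")

_BASE_LABEL = {
    "raw": "Raw",
    "quantile": "Quantile",
    "rank": "Rank",
    "ta": "TA",
    "median": "Median",
    "quotient": "Quotient",
    "taquotient": "TAQuotient",
}


@dataclass(frozen=True)
class NormalizationSpec:
    """One normalization strategy: base method, log flag, per-subclass flag."""

    base: str
    log: bool = False
    per_subclass: bool = False

    def __post_init__(self) -> None:
        if self.base not in BASE_METHODS:
            raise ValueError(f"unknown base method {self.base!r}")
        if self.log and self.base not in _LOG_ELIGIBLE:
            raise ValueError(f"log transform not applicable to {self.base!r}")
        if self.per_subclass and self.base not in _SUBCLASS_ELIGIBLE:
            raise ValueError(f"per-subclass application not applicable to {self.base!r}")

    @property
    def label(self) -> str:
        parts = [_BASE_LABEL[self.base]]
        if self.log:
            parts.append("log")
        if self.per_subclass:
            parts.append("subclass")
        return " ".join(parts)


def _check_complete(x: np.ndarray) -> None:
    if np.isnan(x).any():
        raise ValueError("dataset contains missing values; apply drop_incomplete_samples first")


def total_area(d: GlycomicsDataset) -> GlycomicsDataset:
    """Closure: divide each sample by its total intensity (rows sum to 1)."""
    x = d.values
    _check_complete(x)
    sums = x.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ValueError(f"non-positive total intensity for sample(s): "
                         f"{[d.sample_ids[i] for i in bad]}")
    return d.with_values(x / sums[:, None])


def median_center(d: GlycomicsDataset, mode: str = "per_sample") -> GlycomicsDataset:
    """Subtract a median offset.

    ``per_sample`` (default): each sample's median across glycans is
    subtracted from that sample (constant per-sample offset assumption);
    ``per_glycan``: each glycan's median across samples is subtracted from
    that glycan column.
    """
    x = d.values
    _check_complete(x)
    if mode == "per_sample":
        out = x - np.median(x, axis=1)[:, None]
    elif mode == "per_glycan":
        out = x - np.median(x, axis=0)[None, :]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return d.with_values(out)


def probabilistic_quotient(
    d: GlycomicsDataset, return_factors: bool = False
):
    """Divide each sample by its dilution factor relative to the median reference.

    The reference is the per-glycan median across all samples of the input;
    each sample's dilution factor is the median of its quotients against
    that reference.  Factors are returned for audit when requested.
    """
    x = d.values
    _check_complete(x)
    ref = np.median(x, axis=0)
    bad = np.flatnonzero(ref <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive reference median for glycan(s): {[d.glycan_ids[j] for j in bad]}"
        )
    factors = np.median(x / ref[None, :], axis=1)
    bad = np.flatnonzero(factors <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive dilution factor for sample(s): {[d.sample_ids[i] for i in bad]}"
        )
    out = d.with_values(x / factors[:, None])
    if return_factors:
        return out, factors
    return out


def ta_quotient(d: GlycomicsDataset) -> GlycomicsDataset:
    """Total area closure followed by probabilistic quotient (fixed order)."""
    return probabilistic_quotient(total_area(d))


def quantile_normalize(d: GlycomicsDataset) -> GlycomicsDataset:
    """Force all glycan columns onto a common distribution of rank means.

    Each column is sorted, the mean across columns at every rank position
    is taken, and values are replaced by the mean at their rank; tied
    values receive the average of the tied positions' means.  With no ties
    all columns share one value multiset exactly.
    """
    x = d.values
    _check_complete(x)
    n, p = x.shape
    sorted_means = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(p):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = sorted_means
        # average the assigned means over groups of tied input values
        uniq, inverse = np.unique(col, return_inverse=True)
        if uniq.size < n:
            sums = np.bincount(inverse, weights=assigned)
            counts = np.bincount(inverse)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    return d.with_values(out)


def rank_transform(d: GlycomicsDataset) -> GlycomicsDataset:
    """Replace each glycan column by ranks 1..n across samples (ties averaged)."""
    x = d.values
    _check_complete(x)
    return d.with_values(stats.rankdata(x, axis=0, method="average"))


def log_transform(d: GlycomicsDataset) -> GlycomicsDataset:
    """Natural log, elementwise; every value must be strictly positive."""
    x = d.values
    _check_complete(x)
    if (x <= 0).any():
        i, j = np.argwhere(x <= 0)[0]
        raise ValueError(
            f"non-positive value at sample {d.sample_ids[i]!r}, "
            f"glycan {d.glycan_ids[j]!r}; log transform requires positive data"
        )
    return d.with_values(np.log(x))


def _apply_base(base: str, d: GlycomicsDataset) -> GlycomicsDataset:
    if base == "raw":
        return d
    if base == "quantile":
        return quantile_normalize(d)
    if base == "rank":
        return rank_transform(d)
    if base == "ta":
        return total_area(d)
    if base == "median":
        return median_center(d)
    if base == "quotient":
        return probabilistic_quotient(d)
    if base == "taquotient":
        return ta_quotient(d)
    raise ValueError(f"unknown base method {base!r}")


def _apply_chain(spec: NormalizationSpec, d: GlycomicsDataset) -> GlycomicsDataset:
    out = _apply_base(spec.base, d)
    if spec.log:
        out = log_transform(out)
    return out


def apply_per_subclass(spec: NormalizationSpec, d: GlycomicsDataset) -> GlycomicsDataset:
    """Apply a strategy independently to each IgG subclass column block.

    Glycan metadata must carry subclass labels partitioning the columns;
    blocks are normalized separately and reassembled in the original
    column order.
    """
    sub = d.subclasses()
    x = d.values
    out = np.empty_like(x, dtype=float)
    block_spec = NormalizationSpec(spec.base, spec.log, per_subclass=False)
    for label in sub.unique():
        cols = np.flatnonzero((sub == label).to_numpy())
        block = GlycomicsDataset(
            d.abundance.iloc[:, cols],
            d.sample_meta,
            d.glycan_meta.iloc[cols],
            d.platform,
        )
        out[:, cols] = _apply_chain(block_spec, block).values
    return d.with_values(out)


def apply_strategy(spec: NormalizationSpec, d: GlycomicsDataset) -> GlycomicsDataset:
    """Dispatch one strategy: base method, optional log, optional per-subclass."""
    if spec.per_subclass:
        return apply_per_subclass(spec, d)
    return _apply_chain(spec, d)


def spec_from_label(label: str) -> NormalizationSpec:
    """Parse a strategy label such as ``"TAQuotient log subclass"``."""
    tokens = label.split()
    if not tokens:
        raise ValueError("empty strategy label")
    inverse = {v: k for k, v in _BASE_LABEL.items()}
    if tokens[0] not in inverse:
        raise ValueError(f"unknown base method label {tokens[0]!r}")
    base = inverse[tokens[0]]
    rest = tokens[1:]
    log = "log" in rest
    per_subclass = "subclass" in rest
    if set(rest) - {"log", "subclass"}:
        raise ValueError(f"cannot parse strategy label {label!r}")
    return NormalizationSpec(base, log=log, per_subclass=per_subclass)


def enumerate_strategies(platform: str) -> list[NormalizationSpec]:
    """The evaluated strategy menu for a platform.

    Every platform gets the 13 base strategies (7 methods plus the 6
    log-eligible variants); subclass-resolved LC-ESI-MS data additionally
    get the 10 per-subclass variants, for 23 in total.
    """
    from .dataio import PLATFORMS

    if platform not in PLATFORMS:
        raise ValueError(f"unknown platform {platform!r}")
    specs = [NormalizationSpec(b) for b in BASE_METHODS]
    specs += [NormalizationSpec(b, log=True) for b in _LOG_ELIGIBLE]
    if platform == "lc-esi-ms":
        specs += [NormalizationSpec(b, per_subclass=True) for b in _SUBCLASS_ELIGIBLE]
        specs += [NormalizationSpec(b, log=True, per_subclass=True) for b in _SUBCLASS_ELIGIBLE]
    return specs
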