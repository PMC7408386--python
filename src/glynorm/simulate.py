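"""Synthetic glycomics data with known pathway structure and artifacts.

The generator emulates the data model the evaluation framework assumes:
glycan abundances are log-normal, and on the log scale the samples are
multivariate normal with a sparse precision matrix whose non-zero
off-diagonal entries sit exactly on the edges of a known synthesis
pathway.  Technical contamination is then layered on top of the clean
abundances:

* a per-sample multiplicative dilution factor ``f_i ~ LogNormal(0, sigma_d)``
  (different amounts of biological material per sample), and
* a per-sample additive offset ``o_i ~ Normal(0, sigma_o)``, clipped so
  abundances stay positive.

Closure (total-area scaling) is deliberately *not* part of the generator:
it is one of the strategies under test, not a property of the raw data.
Ground truth (pathway edges, dilution factors, offsets, age slopes) is
returned alongside every dataset so that recovery can be tested.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import GlycomicsDataset
from .glycan_model import (
    GlycanComposition,
    ReferencePathway,
    build_igg_fc_pathway,
    build_mass_pathway,
    composition_mass,
    default_igg_panel,
    enzymatic_edges,
    parse_composition,
)

__all__ = [
    "SimulationConfig",
    "pathway_precision_matrix",
    "sample_abundances",
    "apply_artifacts",
    "generate_benchmark",
    "benchmark_pathway",
]

# Default study conditions: moderate conditional dependence on pathway
# edges, ~20% biological coefficient of variation on the log scale, strong
# dilution (sigma_d = 0.5 spans roughly a 4-fold range of sample amounts),
# no additive offset, adult age range.
DEFAULT_RHO = 0.3
DEFAULT_SIGMA = 0.2
DEFAULT_AGE_RANGE = (18.0, 88.0)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    pathway: ReferencePathway
    n: int = 300
    rho: float = DEFAULT_RHO
    sigma: float = DEFAULT_SIGMA
    sigma_dilution: float = 0.0
    sigma_offset: float = 0.0
    age_slopes: dict[str, float] = field(default_factory=dict)
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE
    baseline_log_range: tuple[float, float] = (np.log(1e2), np.log(1e4))
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.rho < 1):
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        for name in ("sigma", "sigma_dilution", "sigma_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = sorted(set(self.age_slopes) - set(self.pathway.nodes))
        if unknown:
            raise ValueError(f"age slopes refer to unknown glycans: {unknown}")


def pathway_precision_matrix(
    pathway: ReferencePathway, rho: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sparse precision matrix whose support is exactly the pathway edges.

    Starts from the identity with ``-rho * s_ij`` (random signs, seeded via
    ``rng``) at pathway edges, loads the diagonal until the smallest
    eigenvalue exceeds a margin, and rescales back to unit diagonal.  The
    implied partial correlations are non-zero exactly on the edges.
    """
    if not (0 < rho < 1):
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    rng = np.random.default_rng(rng)
    nodes = pathway.nodes
    p = len(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    omega = np.eye(p)
    for a, b in sorted(pathway.edge_set):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        i, j = index[a], index[b]
        omega[i, j] = omega[j, i] = -rho * sign
    margin = 0.05
    eigmin = float(np.linalg.eigvalsh(omega)[0])
    if eigmin < margin:
        omega = omega + (margin - eigmin) * np.eye(p)
        # back to unit diagonal; support and PD-ness are preserved
        d = np.sqrt(np.diag(omega))
        omega = omega / np.outer(d, d)
    return omega


def _truth_dict(config: SimulationConfig) -> dict:
    return {
        "n": config.n,
        "rho": config.rho,
        "sigma": config.sigma,
        "sigma_dilution": config.sigma_dilution,
        "sigma_offset": config.sigma_offset,
        "seed": config.seed,
        "pathway_edges": sorted(map(list, config.pathway.edge_set)),
        "age_slopes": dict(config.age_slopes),
    }


def sample_abundances(config: SimulationConfig) -> tuple[GlycomicsDataset, dict]:
    """Draw clean log-normal abundances with pathway-structured dependence.

    Log abundances are multivariate normal: correlation from the pathway
    precision matrix, per-glycan sd ``sigma``, per-glycan baseline means
    drawn once from ``baseline_log_range``.  Age effects (slope per year,
    log scale) are added for configured glycans, with ages uniform over
    ``age_range``.  Returns the dataset and a ground-truth dictionary.
    """
    rng = np.random.default_rng(config.seed)
    nodes = config.pathway.nodes
    p = len(nodes)
    omega = pathway_precision_matrix(config.pathway, config.rho, rng)
    cov = np.linalg.inv(omega)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)

    mu = rng.uniform(*config.baseline_log_range, size=p)
    age = rng.uniform(*config.age_range, size=config.n)
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal(size=(config.n, p)) @ L.T
    log_x = mu[None, :] + config.sigma * z
    if config.age_slopes:
        mid = 0.5 * (config.age_range[0] + config.age_range[1])
        for name, slope in config.age_slopes.items():
            j = nodes.index(name)
            log_x[:, j] = log_x[:, j] + slope * (age - mid)
    x = np.exp(log_x)

    abund = pd.DataFrame(
        x, index=[f"S{i + 1:05d}" for i in range(config.n)], columns=nodes
    )
    sample_meta = pd.DataFrame({"age": age}, index=abund.index)
    glycan_meta = pd.DataFrame(index=abund.columns)
    subclasses = {
        n: config.pathway.graph.nodes[n].get("subclass") for n in nodes
    }
    if all(v is not None for v in subclasses.values()):
        glycan_meta["subclass"] = [subclasses[n] for n in nodes]
    comps = {n: config.pathway.composition(n) for n in nodes}
    if all(c is not None for c in comps.values()):
        glycan_meta["composition"] = [comps[n].key() for n in nodes]

    dataset = GlycomicsDataset(abund, sample_meta, glycan_meta, "generic")
    truth = _truth_dict(config)
    truth["mu_log"] = mu.tolist()
    truth["omega"] = omega.tolist()
    return dataset, truth


def apply_artifacts(
    clean: GlycomicsDataset, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GlycomicsDataset, dict]:
    """Contaminate clean abundances with dilution and additive offset.

    Each sample is multiplied by ``f_i ~ LogNormal(0, sigma_dilution)`` and
    shifted by ``o_i ~ Normal(0, sigma_offset)``, with values clipped to a
    small positive floor; clipping more than 1% of cells triggers a
    warning.  The true factors/offsets are returned for recovery tests.
    """
    x = clean.values
    if (x <= 0).any():
        raise ValueError("clean abundances must be strictly positive")
    if rng is None:
        rng = np.random.default_rng(
            None if config.seed is None else config.seed + 1_000_003
        )
    n = clean.n_samples
    f = np.exp(rng.normal(0.0, config.sigma_dilution, size=n))
    o = rng.normal(0.0, config.sigma_offset, size=n)
    out = x * f[:, None] + o[:, None]
    floor = 1e-9
    clipped = out < floor
    if clipped.any():
        frac = clipped.mean()
        out = np.where(clipped, floor, out)
        if frac > 0.01:
            warnings.warn(
                f"positivity clipping affected {frac:.1%} of cells", stacklevel=2
            )
    truth = {"dilution_factors": f.tolist(), "offsets": o.tolist()}
    return clean.with_values(out), truth


# --- benchmark shapes -----------------------------------------------------

def benchmark_pathway(shape: str) -> ReferencePathway:
    """Reference pathway for a named platform shape.

    ``lc-esi-ms``: 50 subclass-resolved IgG Fc glycoforms (20/20/10);
    ``uhplc-fld``: 24 peaks, each approximated by one predominant
    biantennary structure; ``maldi-fticr-ms``: 61 mass-merged composition
    nodes from a plausible plasma N-glycan composition grid.
    """
    if shape == "lc-esi-ms":
        return build_igg_fc_pathway(default_igg_panel())
    if shape == "uhplc-fld":
        labels = [
            "G0", "G0F", "G0N", "G0FN",
            "G1", "G1F", "G1N", "G1FN",
            "G2", "G2F", "G2N", "G2FN",
            "G1S1", "G1FS1", "G1NS1", "G1FNS1",
            "G2S1", "G2FS1", "G2NS1", "G2FNS1",
            "G2S2", "G2FS2", "G2NS2", "G2FNS2",
        ]
        comps = {f"GP{i + 1}": parse_composition(lbl, "igg_short")
                 for i, lbl in enumerate(labels)}
        edges = enzymatic_edges(comps)
        attrs = {k: {"composition": v} for k, v in comps.items()}
        return ReferencePathway(list(comps), edges, attrs)
    if shape == "maldi-fticr-ms":
        structures = []
        for h in range(3, 8):
            for n_ in range(2, 7):
                for fuc in range(0, 2):
                    # sialylation bounded by available antennae
                    for s in range(0, max(0, min(4, n_ - 2)) + 1):
                        comp = GlycanComposition(h, n_, fuc, s)
                        structures.append((comp.key(), comp))
        masses = sorted({round(composition_mass(c), 4) for _, c in structures})
        # keep the 61 lightest distinct masses as the measured panel
        measured = {f"{m:.4f}": m for m in masses[:61]}
        pathway, _ = build_mass_pathway(structures, measured)
        return pathway
    raise ValueError(f"unknown platform shape {shape!r}")


_SHAPE_PLATFORM = {
    "lc-esi-ms": "lc-esi-ms",
    "uhplc-fld": "uhplc-fld",
    "maldi-fticr-ms": "maldi-fticr-ms",
}


def generate_benchmark(
    shape: str, outdir=None, **config_kwargs
) -> tuple[GlycomicsDataset, ReferencePathway, dict]:
    """Generate a platform-shaped contaminated dataset with ground truth.

    ``config_kwargs`` are forwarded to :class:`SimulationConfig` (the
    pathway is fixed by ``shape``).  When ``outdir`` is given, writes
    ``abundance.tsv``, ``sample_meta.tsv``, ``glycan_meta.tsv``,
    ``pathway_edges.tsv``, ``pathway_nodes.tsv`` and ``truth.json`` in the
    plain-text formats the dataio module reads.
    """
    pathway = benchmark_pathway(shape)
    config = SimulationConfig(pathway=pathway, **config_kwargs)
    clean, truth = sample_abundances(config)
    contaminated, artifact_truth = apply_artifacts(clean, config)
    truth.update(artifact_truth)
    dataset = GlycomicsDataset(
        contaminated.abundance,
        contaminated.sample_meta,
        contaminated.glycan_meta,
        _SHAPE_PLATFORM[shape],
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        # %.17g is lossless for float64, so a dataio re-read reproduces the
        # matrix exactly
        dataset.abundance.to_csv(outdir / "abundance.tsv", sep="\t", float_format="%.17g")
        dataset.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t", float_format="%.17g")
        dataset.glycan_meta.to_csv(outdir / "glycan_meta.tsv", sep="\t")
        pathway.write_edges_tsv(outdir / "pathway_edges.tsv")
        pathway.write_nodes_tsv(outdir / "pathway_nodes.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return dataset, pathway, truth
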