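"""Glycan compositions and reference synthesis pathways.

N-glycans are built from a small alphabet of monosaccharides: hexoses
(mannose, galactose), N-acetylhexosamines (GlcNAc), deoxyhexose (fucose)
and sialic acid (NeuAc).  At the composition level a glycan is therefore a
4-vector of counts, and a single enzymatic synthesis step adds exactly one
monosaccharide.  This module parses common glycan nomenclatures into
compositions and turns sets of compositions into undirected reference
pathways whose edges are single-addition steps.

Three pathway flavours are supported, matching the three measurement
platforms the package targets:

* subclass-resolved IgG Fc glycopeptides (one pathway copy per IgG
  subclass, optionally cross-linked at identical compositions),
* chromatographic peaks approximated by their predominant structure
  (a plain composition pathway), and
* mass-only panels, where structures sharing a molecular mass are merged
  into a single node and unmeasured masses are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "GlycanComposition",
    "GlycanParseError",
    "MonosaccharideMassTable",
    "RESIDUE_MASSES",
    "ReferencePathway",
    "parse_composition",
    "composition_mass",
    "enzymatic_edges",
    "build_igg_fc_pathway",
    "build_mass_pathway",
    "default_igg_panel",
]


class GlycanParseError(ValueError):
    """Raised when a glycan name cannot be parsed in the declared dialect."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of one glycan or glycopeptide.

    Galactose and mannose are folded into ``hexose``; antenna, core and
    bisecting GlcNAc into ``hexnac``.  ``label`` keeps the original name
    and is ignored when comparing compositions.
    """

    hexose: int
    hexnac: int
    fucose: int
    neuac: int
    label: str = ""

    def __post_init__(self) -> None:
        counts = (self.hexose, self.hexnac, self.fucose, self.neuac)
        if any((not isinstance(c, int)) or c < 0 for c in counts):
            raise ValueError(f"composition counts must be non-negative integers, got {counts}")
        if sum(counts) == 0:
            raise ValueError("composition must contain at least one monosaccharide")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.hexose, self.hexnac, self.fucose, self.neuac)

    def same_composition(self, other: "GlycanComposition") -> bool:
        return self.counts == other.counts

    def distance(self, other: "GlycanComposition") -> int:
        """Total number of monosaccharide additions/removals between two compositions."""
        return sum(abs(a - b) for a, b in zip(self.counts, other.counts))

    def key(self) -> str:
        return "H{}N{}F{}S{}".format(*self.counts)


@dataclass(frozen=True)
class MonosaccharideMassTable:
    """Monoisotopic residue masses in Da (water of condensation removed).

    Only mass *differences/equalities* matter for node merging, so the
    reducing-end water and any constant peptide mass are excluded.
    """

    hexose: float = 162.05282
    hexnac: float = 203.07937
    fucose: float = 146.05791
    neuac: float = 291.09542

    def __post_init__(self) -> None:
        if min(self.hexose, self.hexnac, self.fucose, self.neuac) <= 0:
            raise ValueError("residue masses must be positive")


RESIDUE_MASSES = MonosaccharideMassTable()

# hnfs dialect: single-letter tokens, each at most once, e.g. H5N4F1S1
_HNFS_TOKEN = re.compile(r"([HNFS])(\d+)")
# Oxford-style: optional core fucose, antenna count, optional bisect,
# galactoses, optional sialic acids, e.g. FA2G2S1 / A2BG2S1
_OXFORD = re.compile(r"^(F?)A(\d+)(B?)G(\d+)(?:S(\d+))?$")
# Gx shorthand for biantennary IgG glycoforms, e.g. G0F, G1FN, G2FS2
_GX = re.compile(r"^G([0-2])(F?)(N?)(?:S(\d*))?$")


def parse_composition(name: str, dialect: str = "hnfs") -> GlycanComposition:
    """Parse a glycan name into monosaccharide counts.

    Parameters
    ----------
    name:
        Glycan name, e.g. ``"H5N4F1S1"`` (hnfs) or ``"FA2G2S1"`` / ``"G0F"``
        (igg_short).
    dialect:
        ``"hnfs"`` — explicit H/N/F/S counts; ``"igg_short"`` — Oxford-style
        or Gx-style short names for biantennary IgG glycoforms, expanded on
        the Man3GlcNAc2 core.
    """
    token = name.strip()
    if dialect == "hnfs":
        pos = 0
        counts = {}
        for m in _HNFS_TOKEN.finditer(token):
            if m.start() != pos:
                raise GlycanParseError(
                    f"cannot parse {name!r}: unexpected {token[pos:m.start()]!r}"
                )
            letter = m.group(1)
            if letter in counts:
                raise GlycanParseError(f"cannot parse {name!r}: duplicate token {letter!r}")
            counts[letter] = int(m.group(2))
            pos = m.end()
        if pos != len(token) or not counts:
            raise GlycanParseError(f"cannot parse {name!r}: unexpected {token[pos:]!r}")
        return GlycanComposition(
            hexose=counts.get("H", 0),
            hexnac=counts.get("N", 0),
            fucose=counts.get("F", 0),
            neuac=counts.get("S", 0),
            label=name,
        )
    if dialect == "igg_short":
        m = _OXFORD.match(token)
        if m:
            fuc, ant, bis, gal, sia = m.groups()
            return GlycanComposition(
                hexose=3 + int(gal),
                hexnac=2 + int(ant) + (1 if bis else 0),
                fucose=1 if fuc else 0,
                neuac=int(sia) if sia else 0,
                label=name,
            )
        m = _GX.match(token)
        if m:
            gal, fuc, bis, sia = m.groups()
            # biantennary core: Man3 + 2 core GlcNAc + 2 antenna GlcNAc
            neuac = 0 if sia is None else (1 if sia == "" else int(sia))
            return GlycanComposition(
                hexose=3 + int(gal),
                hexnac=4 + (1 if bis else 0),
                fucose=1 if fuc else 0,
                neuac=neuac,
                label=name,
            )
        raise GlycanParseError(f"cannot parse {name!r} as igg_short")
    raise ValueError(f"unknown dialect {dialect!r}")


def composition_mass(
    c: GlycanComposition, masses: MonosaccharideMassTable = RESIDUE_MASSES
) -> float:
    """Residue-sum mass in Da (constant offsets such as water excluded)."""
    return (
        c.hexose * masses.hexose
        + c.hexnac * masses.hexnac
        + c.fucose * masses.fucose
        + c.neuac * masses.neuac
    )


def _as_mapping(compositions) -> dict[str, GlycanComposition]:
    if isinstance(compositions, Mapping):
        return dict(compositions)
    out: dict[str, GlycanComposition] = {}
    for key, comp in compositions:
        if key in out:
            raise ValueError(f"duplicate glycan id {key!r}")
        out[key] = comp
    return out


def enzymatic_edges(compositions) -> set[tuple[str, str]]:
    """Single-monosaccharide-addition edges among a set of compositions.

    Two glycans are connected iff their compositions differ by exactly one
    unit in exactly one of hexose/HexNAc/fucose/NeuAc.  Accepts a mapping
    ``id -> GlycanComposition`` or an iterable of ``(id, composition)``
    pairs (duplicate ids are rejected).
    """
    comp = _as_mapping(compositions)
    if len(comp) < 2:
        raise ValueError("need at least two compositions")
    ids = sorted(comp)
    edges: set[tuple[str, str]] = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if comp[a].distance(comp[b]) == 1:
                edges.add((a, b))
    return edges


class ReferencePathway:
    """Undirected glycan synthesis pathway over named nodes.

    Edges represent single enzymatic steps; the graph is simple (no
    self-loops) and edges are stored canonically as sorted pairs.
    Node attributes may carry a :class:`GlycanComposition` and/or a mass.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]] = (),
        node_attrs: Mapping[str, dict] | None = None,
    ) -> None:
        g = nx.Graph()
        node_list = list(nodes)
        if len(set(node_list)) != len(node_list):
            raise ValueError("duplicate pathway node names")
        g.add_nodes_from(node_list)
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop at node {a!r}")
            if a not in g or b not in g:
                missing = {a, b} - set(g)
                raise ValueError(f"edge endpoint(s) not in node list: {sorted(missing)}")
            g.add_edge(a, b)
        if node_attrs:
            for name, attrs in node_attrs.items():
                if name not in g:
                    raise ValueError(f"attributes given for unknown node {name!r}")
                g.nodes[name].update(attrs)
        self.graph = g

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def composition(self, node: str) -> GlycanComposition | None:
        return self.graph.nodes[node].get("composition")

    def mass(self, node: str) -> float | None:
        return self.graph.nodes[node].get("mass")

    def subgraph(self, nodes: Iterable[str]) -> "ReferencePathway":
        keep = list(nodes)
        sub = self.graph.subgraph(keep)
        return ReferencePathway(keep, sub.edges, {n: dict(sub.nodes[n]) for n in keep})

    # --- plain-text export / import -------------------------------------

    def write_edges_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node1\tnode2\n")
            for a, b in sorted(self.edge_set):
                fh.write(f"{a}\t{b}\n")

    def write_nodes_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tcomposition\tmass\tsubclass\n")
            for n in self.nodes:
                comp = self.composition(n)
                mass = self.mass(n)
                fh.write(
                    "{}\t{}\t{}\t{}\n".format(
                        n,
                        comp.key() if comp else "",
                        "" if mass is None else f"{mass:.5f}",
                        self.graph.nodes[n].get("subclass", ""),
                    )
                )

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for n in self.nodes:
            attrs = {}
            comp = self.composition(n)
            if comp is not None:
                attrs["composition"] = comp.key()
            mass = self.mass(n)
            if mass is not None:
                attrs["mass"] = float(mass)
            sub = self.graph.nodes[n].get("subclass")
            if sub is not None:
                attrs["subclass"] = sub
            g.add_node(n, **attrs)
        g.add_edges_from(self.graph.edges)
        nx.write_graphml(g, path)


def build_igg_fc_pathway(
    glycans: Sequence[tuple[str, str, GlycanComposition]],
    include_cross_subclass: bool = False,
) -> ReferencePathway:
    """Subclass-resolved IgG Fc glycopeptide pathway.

    Each glycan is given as ``(label, subclass, composition)`` with subclass
    in {IgG1, IgG2/3, IgG4}.  The same synthesis rules apply within every
    subclass; node ids are ``"<subclass>_<label>"``.  With
    ``include_cross_subclass`` identical compositions in different
    subclasses are additionally connected (off by default — the platform
    measures subclasses independently).
    """
    valid = {"IgG1", "IgG2/3", "IgG4"}
    by_subclass: dict[str, dict[str, GlycanComposition]] = {}
    node_attrs: dict[str, dict] = {}
    nodes: list[str] = []
    for label, subclass, comp in glycans:
        if subclass not in valid:
            raise ValueError(f"unknown IgG subclass {subclass!r}")
        node = f"{subclass}_{label}"
        block = by_subclass.setdefault(subclass, {})
        if label in block:
            raise ValueError(f"duplicate label {label!r} within subclass {subclass}")
        block[label] = comp
        nodes.append(node)
        node_attrs[node] = {"composition": comp, "subclass": subclass}

    edges: set[tuple[str, str]] = set()
    for subclass, block in by_subclass.items():
        if len(block) >= 2:
            for a, b in enzymatic_edges(block):
                edges.add(tuple(sorted((f"{subclass}_{a}", f"{subclass}_{b}"))))
    if include_cross_subclass:
        items = [(n, node_attrs[n]["composition"], node_attrs[n]["subclass"]) for n in nodes]
        for i, (na, ca, sa) in enumerate(items):
            for nb, cb, sb in items[i + 1 :]:
                if sa != sb and ca.same_composition(cb):
                    edges.add(tuple(sorted((na, nb))))
    return ReferencePathway(nodes, edges, node_attrs)


def build_mass_pathway(
    structures: Sequence[tuple[str, GlycanComposition]],
    measured_masses: Mapping[str, float] | Sequence[float],
    masses: MonosaccharideMassTable = RESIDUE_MASSES,
    tol: float = 0.5,
    bridge_removed: bool = False,
) -> tuple[ReferencePathway, list[str]]:
    """Mass-merged composition pathway for mass-only platforms.

    Builds the full single-addition pathway over ``structures``, merges all
    structures of equal mass into one node (union of incident edges,
    self-loops dropped), and keeps only nodes whose mass matches a measured
    mass within ``tol`` Da.  With ``bridge_removed`` on, neighbours of a
    removed node are connected directly (applied transitively through runs
    of removed nodes); off by default, so edges through unmeasured masses
    are lost.

    Returns the pathway (nodes named by measured-mass key) and the list of
    measured keys that matched no structure; those are kept as degree-0
    nodes and reported with a warning.
    """
    import warnings

    seen = set()
    for label, _ in structures:
        if label in seen:
            raise ValueError(f"duplicate structure label {label!r}")
        seen.add(label)

    if isinstance(measured_masses, Mapping):
        measured = dict(measured_masses)
    else:
        measured = {f"{m:.4f}": float(m) for m in measured_masses}

    comp_map = {label: comp for label, comp in structures}
    full_edges = enzymatic_edges(comp_map) if len(comp_map) >= 2 else set()

    # merge structures of equal mass (exact at machine resolution of the
    # residue-sum; grouping key rounded to 1e-4 Da)
    mass_of = {label: composition_mass(comp, masses) for label, comp in comp_map.items()}
    group_of: dict[str, str] = {}
    group_mass: dict[str, float] = {}
    for label in comp_map:
        key = f"{mass_of[label]:.4f}"
        group_of[label] = key
        group_mass[key] = mass_of[label]

    merged = nx.Graph()
    merged.add_nodes_from(group_mass)
    for a, b in full_edges:
        ga, gb = group_of[a], group_of[b]
        if ga != gb:
            merged.add_edge(ga, gb)

    # resolve each merged node to a measured-mass key within tolerance
    resolved: dict[str, str] = {}
    for gkey, gmass in group_mass.items():
        best = None
        for mkey, mmass in measured.items():
            d = abs(gmass - mmass)
            if d <= tol and (best is None or d < best[0]):
                best = (d, mkey)
        if best is not None:
            resolved[gkey] = best[1]

    removed = [g for g in merged.nodes if g not in resolved]
    work = merged.copy()
    if bridge_removed:
        for node in removed:
            nbrs = list(work.neighbors(node))
            for i, a in enumerate(nbrs):
                for b in nbrs[i + 1 :]:
                    if a != b:
                        work.add_edge(a, b)
            work.remove_node(node)
    else:
        work.remove_nodes_from(removed)

    final = nx.Graph()
    final.add_nodes_from(measured)
    for a, b in work.edges:
        ka, kb = resolved[a], resolved[b]
        if ka != kb:
            final.add_edge(ka, kb)

    matched_keys = set(resolved.values())
    unmatched = sorted(k for k in measured if k not in matched_keys)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} measured mass(es) matched no structure and remain "
            f"isolated: {unmatched}",
            stacklevel=2,
        )
    node_attrs = {k: {"mass": v} for k, v in measured.items()}
    pathway = ReferencePathway(list(measured), final.edges, node_attrs)
    return pathway, unmatched


# Representative biantennary IgG Fc glycoform panels.  The subclass split
# (20 / 20 / 10 glycoforms) matches the shape of subclass-resolved Fc
# glycopeptide panels; the label sets are a curated synthetic stand-in for
# benchmark construction, not a transcription of any published panel.
_IGG1_LABELS = [
    "G0", "G0F", "G0N", "G0FN",
    "G1", "G1F", "G1N", "G1FN",
    "G2", "G2F", "G2N", "G2FN",
    "G1S1", "G1FS1", "G1FNS1",
    "G2S1", "G2FS1", "G2FNS1",
    "G2S2", "G2FS2",
]
_IGG4_LABELS = [
    "G0", "G0F", "G1", "G1F", "G2", "G2F",
    "G0FN", "G1FN", "G1FS1", "G2FS1",
]


def default_igg_panel() -> list[tuple[str, str, GlycanComposition]]:
    """50-glycoform panel: 20 IgG1, 20 IgG2/3, 10 IgG4 (synthetic stand-in)."""
    panel = []
    for subclass, labels in (
        ("IgG1", _IGG1_LABELS),
        ("IgG2/3", _IGG1_LABELS),
        ("IgG4", _IGG4_LABELS),
    ):
        for label in labels:
            panel.append((label, subclass, parse_composition(label, "igg_short")))
    return panel
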