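"""Subunit adjacency from cross-link evidence, and Ca-distance restraints.

A cross-linked gel product or validated peptide pair connects two (rarely
three) subunits; the collection forms a hypergraph whose pairwise
projection is the nearest-neighbor map of the complex.  Cross-links
identified at residue level can additionally be checked against structure
coordinates: the DSS spacer constrains linked lysine Ca atoms to roughly
26-30 A, so a mapped pair farther apart than the threshold (30 A by
default) is incompatible with the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "CrossLinkRecord",
    "TopologyGraph",
    "DistanceRestraintResult",
    "load_table2",
    "build_graph",
    "map_peptide_to_chain",
    "read_structure_chains",
    "check_restraint",
]


@dataclass(frozen=True)
class CrossLinkRecord:
    """One cross-linked product: 2-3 member subunits plus provenance."""

    record_id: str
    members: frozenset
    linkers: tuple = ()
    methods: tuple = ()  # "I" (immunoblot) and/or "M" (mass spectrometry)
    apparent_kd: float | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(
                f"record {self.record_id!r} has fewer than 2 members")


class TopologyGraph:
    """Hypergraph of subunit adjacency evidence."""

    def __init__(self, records):
        ids = [r.record_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids")
        self.records = list(records)
        self.nodes = sorted(set().union(*(r.members for r in records))) \
            if records else []

    @property
    def hyperedges(self):
        return [(r.record_id, r.members) for r in self.records]

    def pairwise(self) -> nx.MultiGraph:
        """Pairwise projection; edges from triples carry expanded=True."""
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        from itertools import combinations

        for r in self.records:
            expanded = len(r.members) > 2
            for a, b in combinations(sorted(r.members), 2):
                g.add_edge(a, b, record_id=r.record_id, expanded=expanded,
                           linkers=r.linkers, methods=r.methods)
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (d["record_id"], a, b, ",".join(d["linkers"]),
             ",".join(d["methods"]), d["expanded"])
            for a, b, d in self.pairwise().edges(data=True)
        ]
        return pd.DataFrame(rows, columns=[
            "record_id", "subunit_a", "subunit_b", "linkers", "methods",
            "expanded_from_triple"])


def load_table2(path=None) -> list[CrossLinkRecord]:
    """Load the packaged cross-linked-product fixture (or a file like it)."""
    if path is None:
        source = resources.files("xlscout.data") / "table2_crosslinks.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for r in df.itertuples():
        kd = None if str(r.apparent_kd) in ("n.d.", "nan") else float(r.apparent_kd)
        records.append(CrossLinkRecord(
            record_id=str(r.record_id),
            members=frozenset(str(r.members).split(";")),
            linkers=tuple(str(r.linkers).split(",")),
            methods=tuple(str(r.methods).split(",")),
            apparent_kd=kd,
        ))
    return records


def build_graph(records) -> TopologyGraph:
    """Assemble the adjacency hypergraph from cross-link records."""
    return TopologyGraph(records)


def map_peptide_to_chain(peptide_seq: str, link_pos: int, chain_seq: str,
                         min_identity: float = 0.6):
    """Locate a cross-linked peptide on a structure chain.

    Exact substring match is preferred; otherwise the best gapless sliding
    alignment with at least ``min_identity`` identity over the peptide
    length is used (the cross-species analogue of a short-query protein
    BLAST).  Returns ``(chain_residue_index, method)`` with a 1-based index
    of the residue aligned to ``link_pos``, or ``None`` when no placement
    reaches the identity threshold.  Multiple equally good placements raise
    an ambiguity error listing the offsets.
    """
    if not 1 <= link_pos <= len(peptide_seq):
        raise ValueError("link position outside the peptide")
    n, m = len(peptide_seq), len(chain_seq)
    if n > m:
        return None
    exact = [i for i in range(m - n + 1) if chain_seq[i:i + n] == peptide_seq]
    if len(exact) > 1:
        raise ValueError(
            f"ambiguous placement: exact matches at offsets {exact}")
    if exact:
        return exact[0] + link_pos, "exact"
    best_score, best_offsets = 0, []
    for i in range(m - n + 1):
        score = sum(a == b for a, b in zip(peptide_seq, chain_seq[i:i + n]))
        if score > best_score:
            best_score, best_offsets = score, [i]
        elif score == best_score:
            best_offsets.append(i)
    if best_score / n < min_identity:
        return None
    if len(best_offsets) > 1:
        raise ValueError(
            f"ambiguous placement: equally good alignments at offsets {best_offsets}")
    return best_offsets[0] + link_pos, "aligned"


def read_structure_chains(path):
    """Read polymer chains from a PDB/mmCIF file.

    Returns ``{chain_id: (sequence, [CA coordinates or None])}`` using one
    entry per polymer residue.
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    chains = {}
    for chain in model:
        seq, cas = [], []
        for residue in chain:
            code = gemmi.find_tabulated_residue(residue.name)
            if code is None or not code.is_amino_acid():
                continue
            one = gemmi.find_tabulated_residue(residue.name).one_letter_code.upper()
            seq.append(one if one.isalpha() else "X")
            ca = residue.find_atom("CA", "*")
            cas.append((ca.pos.x, ca.pos.y, ca.pos.z) if ca is not None else None)
        if seq:
            chains[chain.name] = ("".join(seq), cas)
    return chains


@dataclass(frozen=True)
class DistanceRestraintResult:
    record_id: str
    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    distance: float
    threshold: float
    satisfied: bool
    mapping_method: str
    in_soft_band: bool = False  # 26-30 A: satisfied but near the limit


def check_restraint(chains, mapping_a, mapping_b, threshold: float = 30.0,
                    record_id: str = "", soft_band=(26.0, 30.0)) -> DistanceRestraintResult:
    """Euclidean Ca-Ca distance between two mapped residues.

    ``mapping_a``/``mapping_b`` are ``(chain_id, residue_index, method)``
    with 1-based residue indices into the chain's polymer sequence.
    """
    coords = []
    methods = []
    for chain_id, idx, method in (mapping_a, mapping_b):
        seq, cas = chains[chain_id]
        if not 1 <= idx <= len(cas):
            raise ValueError(f"residue {idx} outside chain {chain_id!r}")
        ca = cas[idx - 1]
        if ca is None:
            raise ValueError(f"missing Ca for chain {chain_id!r} residue {idx}")
        coords.append(ca)
        methods.append(method)
    d = math.dist(coords[0], coords[1])
    return DistanceRestraintResult(
        record_id=record_id,
        chain_a=mapping_a[0], residue_a=mapping_a[1],
        chain_b=mapping_b[0], residue_b=mapping_b[1],
        distance=d, threshold=threshold, satisfied=d <= threshold,
        mapping_method="exact" if all(m == "exact" for m in methods) else "aligned",
        in_soft_band=soft_band[0] <= d <= soft_band[1],
    )
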