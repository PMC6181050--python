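"""Cross-linker chemistry and enumeration of cross-link candidates.

The workhorse linker is isotope-coded disuccinimidyl suberate (DSS d0/d12):
an amine-reactive homobifunctional reagent applied as a 1:1 light/heavy
mixture whose heavy form carries twelve deuteriums, shifting every
cross-linked precursor by 12.07532 Da.  The light bridge residual is the
suberate spacer C8H10O2, 138.06808 Da monoisotopic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .proteome import Peptide

__all__ = [
    "DSS_HEAVY_DELTA",
    "DSS_BRIDGE_LIGHT",
    "CrossLinker",
    "DSS",
    "CrossLinkCandidate",
    "PeptideIndex",
    "link_sites",
    "enumerate_candidates",
]

DSS_HEAVY_DELTA = 12.07532  # Da, d12 - d0
DSS_BRIDGE_LIGHT = 138.06808  # Da, C8H10O2


@dataclass(frozen=True)
class CrossLinker:
    """An amine-reactive homobifunctional cross-linker definition."""

    name: str
    reactive_residues: frozenset = frozenset({"K"})
    protein_nterm: bool = True
    bridge_mass_light: float = DSS_BRIDGE_LIGHT
    heavy_delta: float = DSS_HEAVY_DELTA

    @property
    def bridge_mass_heavy(self) -> float:
        return self.bridge_mass_light + self.heavy_delta

    def bridge_mass(self, isotope_form: str) -> float:
        if isotope_form == "light":
            return self.bridge_mass_light
        if isotope_form == "heavy":
            return self.bridge_mass_heavy
        raise ValueError(f"unknown isotope form {isotope_form!r}")


DSS = CrossLinker(name="DSS")


@dataclass(frozen=True)
class CrossLinkCandidate:
    """Two peptides joined by an intact cross-link bridge.

    The pair is unordered; by convention alpha <= beta lexicographically on
    (protein_id, start, sequence).  Link positions are 1-based within each
    peptide.
    """

    peptide_alpha: Peptide
    peptide_beta: Peptide
    link_pos_alpha: int
    link_pos_beta: int
    isotope_form: str
    theoretical_neutral_mass: float
    linker: CrossLinker = field(default=DSS, compare=False)

    @property
    def key(self):
        """Identity of the linked residue pair (used for step-2 validation)."""
        a = (self.peptide_alpha.protein_id, self.peptide_alpha.start,
             self.peptide_alpha.sequence, self.link_pos_alpha)
        b = (self.peptide_beta.protein_id, self.peptide_beta.start,
             self.peptide_beta.sequence, self.link_pos_beta)
        return tuple(sorted([a, b]))


def link_sites(peptide: Peptide, linker: CrossLinker = DSS,
               protein_length: int | None = None) -> list[int]:
    """Reactive positions (1-based) on a tryptic peptide.

    Lysines are reactive except the peptide's C-terminal residue: a cleaved
    C-terminal K cannot carry the linker or trypsin would not have cut
    there.  The exception is the protein C-terminus (no cut involved),
    allowed when ``protein_length`` shows the peptide reaches it.  The
    alpha-amine of the protein N-terminal peptide adds position 1.
    """
    n = len(peptide.sequence)
    sites = []
    if linker.protein_nterm and peptide.start == 1:
        sites.append(1)
    for i, aa in enumerate(peptide.sequence, start=1):
        if aa not in linker.reactive_residues:
            continue
        if i == n and not (protein_length is not None and peptide.end == protein_length):
            continue  # cleaved C-terminal K
        if i not in sites:
            sites.append(i)
    return sites


def _pep_sort_key(p: Peptide):
    return (p.protein_id, p.start, p.sequence, p.modifications)


class PeptideIndex:
    """Mass-sorted index of linkable peptides for candidate lookup."""

    def __init__(self, entries):
        """``entries``: iterable of (peptide, link_positions) pairs."""
        items = []
        for pep, positions in entries:
            if positions:
                items.append((pep.mass, pep, tuple(positions)))
        items.sort(key=lambda t: (t[0],) + _pep_sort_key(t[1]))
        self._masses = [t[0] for t in items]
        self._items = items

    @classmethod
    def from_proteins(cls, proteins, linker: CrossLinker = DSS,
                      max_missed: int = 3, min_len: int = 4, max_len: int = 40,
                      variable_mods: bool = True, max_ox: int = 2):
        """Digest proteins and index every linkable (modified) peptide.

        Variable modification: oxidation of Met, up to ``max_ox`` per
        peptide.
        """
        from itertools import combinations

        from .proteome import MET_OXIDATION, digest

        entries = []
        for prot in proteins:
            for pep in digest(prot, max_missed=max_missed,
                              min_len=min_len, max_len=max_len):
                positions = link_sites(pep, linker, protein_length=len(prot))
                if not positions:
                    continue
                entries.append((pep, positions))
                if variable_mods:
                    mets = [i + 1 for i, aa in enumerate(pep.sequence) if aa == "M"]
                    for k in range(1, min(max_ox, len(mets)) + 1):
                        for combo in combinations(mets, k):
                            mods = tuple(
                                (m, MET_OXIDATION, "Oxidation") for m in combo
                            )
                            entries.append(
                                (Peptide(pep.protein_id, pep.start, pep.end,
                                         pep.sequence, pep.missed_cleavages,
                                         mods), positions)
                            )
        return cls(entries)

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    def range(self, lo: float, hi: float):
        """Indexed entries with mass in [lo, hi]."""
        i = bisect.bisect_left(self._masses, lo)
        j = bisect.bisect_right(self._masses, hi)
        return self._items[i:j]


def enumerate_candidates(
    index: PeptideIndex,
    observed_neutral_mass: float,
    isotope_form: str = "light",
    tol_ppm: float = 10.0,
    linker: CrossLinker = DSS,
) -> list[CrossLinkCandidate]:
    """All peptide pairs whose cross-linked mass matches the precursor.

    Returns every unordered pair (a peptide may pair with itself, and
    intra-protein pairs are allowed) with at least one reactive site on
    each peptide, such that mass(alpha) + mass(beta) + bridge matches
    ``observed_neutral_mass`` within ``tol_ppm``.  One candidate is emitted
    per pair and site combination.  Order is deterministic: by theoretical
    mass, then lexicographic.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    bridge = linker.bridge_mass(isotope_form)
    # the acceptance test |theo - observed| <= theo * rel is equivalent to
    # observed/(1+rel) <= theo <= observed/(1-rel); bound the pair-mass
    # search window accordingly
    rel = min(tol_ppm * 1e-6, 0.5)
    lo_pair = observed_neutral_mass / (1 + rel) - bridge
    hi_pair = observed_neutral_mass / (1 - rel) - bridge
    out: list[CrossLinkCandidate] = []
    for mass_a, pep_a, sites_a in index:
        if mass_a > hi_pair / 2:
            break  # alpha is the lighter partner; avoids double counting
        for mass_b, pep_b, sites_b in index.range(lo_pair - mass_a,
                                                  hi_pair - mass_a):
            ka, kb = _pep_sort_key(pep_a), _pep_sort_key(pep_b)
            if (mass_b, kb) < (mass_a, ka):
                continue
            theo = mass_a + mass_b + bridge
            if abs(theo - observed_neutral_mass) > theo * tol_ppm * 1e-6:
                continue
            for sa in sites_a:
                for sb in sites_b:
                    if (mass_a, ka) == (mass_b, kb) and sb < sa:
                        continue  # same peptide with itself: unordered sites
                    out.append(CrossLinkCandidate(
                        peptide_alpha=pep_a, peptide_beta=pep_b,
                        link_pos_alpha=sa, link_pos_beta=sb,
                        isotope_form=isotope_form,
                        theoretical_neutral_mass=theo, linker=linker))
    out.sort(key=lambda c: (c.theoretical_neutral_mass,
                            _pep_sort_key(c.peptide_alpha),
                            _pep_sort_key(c.peptide_beta),
                            c.link_pos_alpha, c.link_pos_beta))
    return out
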