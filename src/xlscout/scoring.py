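"""Fragment generation, peak matching, Poisson E-value scoring and the
two-step cross-link search.

The score follows the classic probability model used for linear peptide
search engines: under a null in which observed fragment peaks fall
uniformly at random over the scored mass range, the number of theoretical
ions matched by chance is approximately Poisson with mean
``mu = n_theoretical * p_match``, where ``p_match`` is the probability that
a random peak lands within the fragment tolerance of a given theoretical
ion.  The p-value is the Poisson survival probability
``P[X >= n_matched]`` and the E-value multiplies it by the number of
candidates competing for the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from scipy.stats import poisson as _poisson

from .chemistry import (DSS, CrossLinkCandidate, CrossLinker, PeptideIndex,
                        enumerate_candidates)
from .proteome import RESIDUE_MASS, WATER, Peptide

__all__ = [
    "FragmentIon",
    "FragTol",
    "ScoredMatch",
    "CrossLinkIdentification",
    "LinearCandidate",
    "theoretical_fragments",
    "linear_fragments",
    "match_fragments",
    "poisson_pvalue",
    "score_spectrum",
    "two_step_search",
    "SearchConfig",
]


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical b- or y-ion of one peptide of a cross-linked pair.

    ``carries_partner`` marks fragments spanning the linked residue; their
    mass includes the bridge and the full partner peptide.
    """

    origin: str  # "alpha" | "beta" | "linear"
    series: str  # "b" | "y"
    index: int
    carries_partner: bool
    neutral_mass: float


@dataclass(frozen=True)
class FragTol:
    """Dual fragment tolerance: a peak matches within EITHER bound."""

    abs_da: float = 0.05
    ppm: float = 10.0

    def window(self, mass: float) -> float:
        return max(self.abs_da, mass * self.ppm * 1e-6)


def _prefix_masses(peptide: Peptide) -> list[float]:
    """Cumulative residue masses including modifications, index 1..n."""
    mods = {}
    for pos, delta, _ in peptide.modifications:
        mods[pos] = mods.get(pos, 0.0) + delta
    acc, out = 0.0, [0.0]
    for i, aa in enumerate(peptide.sequence, start=1):
        acc += RESIDUE_MASS[aa] + mods.get(i, 0.0)
        out.append(acc)
    return out


def linear_fragments(peptide: Peptide) -> list[FragmentIon]:
    """Plain b/y series of an unlinked peptide (neutral masses)."""
    pre = _prefix_masses(peptide)
    n = len(peptide)
    total = pre[n]
    out = []
    for i in range(1, n):
        out.append(FragmentIon("linear", "b", i, False, pre[i]))
        out.append(FragmentIon("linear", "y", i, False, total - pre[n - i] + WATER))
    return out


def theoretical_fragments(candidate: CrossLinkCandidate) -> list[FragmentIon]:
    """b/y ions for both peptides of a cross-linked pair.

    For each peptide of length n the series b1..b(n-1) and y1..y(n-1) are
    produced; ions spanning the linked residue gain the bridge mass plus
    the intact partner peptide.  Total count is 2(n_a - 1) + 2(n_b - 1).
    """
    bridge = candidate.linker.bridge_mass(candidate.isotope_form)
    out = []
    for origin, pep, link_pos, partner in (
        ("alpha", candidate.peptide_alpha, candidate.link_pos_alpha,
         candidate.peptide_beta),
        ("beta", candidate.peptide_beta, candidate.link_pos_beta,
         candidate.peptide_alpha),
    ):
        pre = _prefix_masses(pep)
        n = len(pep)
        total = pre[n]
        partner_add = bridge + partner.mass
        for i in range(1, n):
            b_spans = i >= link_pos
            y_spans = i >= n - link_pos + 1
            b_mass = pre[i] + (partner_add if b_spans else 0.0)
            y_mass = total - pre[n - i] + WATER + (partner_add if y_spans else 0.0)
            out.append(FragmentIon(origin, "b", i, b_spans, b_mass))
            out.append(FragmentIon(origin, "y", i, y_spans, y_mass))
    return out


def match_fragments(theoretical, neutral_peaks, frag_tol: FragTol = FragTol()):
    """Count theoretical ions explained by deconvoluted peaks.

    One-to-one greedy assignment: candidate (ion, peak) pairs within the
    dual tolerance are taken in order of increasing mass error, each ion
    and each peak used at most once.  Returns (n_matched, n_theoretical).
    """
    masses = [f.neutral_mass for f in theoretical]
    peaks = [m for m, _ in neutral_peaks.peaks] if hasattr(neutral_peaks, "peaks") \
        else list(neutral_peaks)
    pairs = []
    import bisect
    peaks_sorted = sorted(peaks)
    for ti, tm in enumerate(masses):
        w = frag_tol.window(tm)
        i = bisect.bisect_left(peaks_sorted, tm - w)
        j = bisect.bisect_right(peaks_sorted, tm + w)
        for pi in range(i, j):
            pairs.append((abs(peaks_sorted[pi] - tm), ti, pi))
    pairs.sort()
    used_t, used_p = set(), set()
    for _, ti, pi in pairs:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
    return len(used_t), len(masses)


def poisson_pvalue(n_matched: int, n_theoretical: int, p_match: float) -> float:
    """P[Poisson(n_theoretical * p_match) >= n_matched]."""
    if not 0.0 <= p_match <= 1.0:
        raise ValueError("p_match must lie in [0, 1]")
    if n_matched <= 0:
        return 1.0
    mu = n_theoretical * p_match
    return float(_poisson.sf(n_matched - 1, mu))


@dataclass(frozen=True)
class ScoredMatch:
    candidate: object  # CrossLinkCandidate | LinearCandidate
    n_matched: int
    n_theoretical: int
    p_match: float
    p_value: float
    e_value: float
    scan_id: str


@dataclass(frozen=True)
class LinearCandidate:
    """A single (non-cross-linked) peptide explaining a precursor mass.

    Used in step-2 validation: a convincing linear explanation can
    displace a tentative cross-link.
    """

    peptide: Peptide
    theoretical_neutral_mass: float

    @property
    def key(self):
        return (("linear", self.peptide.protein_id, self.peptide.start,
                 self.peptide.sequence, self.peptide.modifications),)


def _candidate_sort_key(cand):
    if isinstance(cand, LinearCandidate):
        return (1,) + cand.key
    return (0,) + cand.key


def estimate_p_match(neutral_peaks, frag_tol: FragTol, mass_range: float) -> float:
    """Probability a random peak explains a given theoretical ion.

    Constant-density estimate: observed peak count x 2 x effective Da
    tolerance divided by the scored mass range.
    """
    n_peaks = len(neutral_peaks.peaks)
    if n_peaks == 0 or mass_range <= 0:
        return 0.0
    eff = frag_tol.window(mass_range / 2.0)
    return min(1.0, n_peaks * 2.0 * eff / mass_range)


def score_spectrum(neutral_peaks, candidates, frag_tol: FragTol = FragTol()):
    """Score candidates against a deconvoluted spectrum, best first.

    Ranked ascending by E-value, ties broken by matched-ion count (more is
    better) then lexicographically for determinism.
    """
    if not candidates:
        return []
    mass_range = max(neutral_peaks.precursor_neutral_mass, 1.0) - 100.0
    mass_range = max(mass_range, 1.0)
    p_match = estimate_p_match(neutral_peaks, frag_tol, mass_range)
    n_cands = len(candidates)
    out = []
    for cand in candidates:
        frags = (linear_fragments(cand.peptide)
                 if isinstance(cand, LinearCandidate)
                 else theoretical_fragments(cand))
        n_m, n_t = match_fragments(frags, neutral_peaks, frag_tol)
        p = poisson_pvalue(n_m, n_t, p_match)
        out.append(ScoredMatch(cand, n_m, n_t, p_match, p,
                               p * n_cands, neutral_peaks.scan_id))
    out.sort(key=lambda s: (s.e_value, -s.n_matched,
                            _candidate_sort_key(s.candidate)))
    return out


@dataclass(frozen=True)
class CrossLinkIdentification:
    """A validated cross-link with absolute residue coordinates."""

    protein_a: str
    residue_a: int  # absolute 1-based position of the linked residue
    protein_b: str
    residue_b: int
    peptide_a: str
    peptide_b: str
    scan_id: str
    isotope_evidence: str  # light | heavy | paired
    e_value: float
    n_matched: int
    n_theoretical: int
    status: str = "validated"
    best_competitor: str = ""


@dataclass
class SearchConfig:
    precursor_ppm: float = 10.0
    frag_tol: FragTol = field(default_factory=FragTol)
    e_max: float = 0.01
    max_missed: int = 3
    min_len: int = 4
    max_len: int = 40
    max_precursor_charge: int = 6
    linker: CrossLinker = field(default_factory=lambda: DSS)
    validation_mode: str = "top_ranked"  # or "evalue_factor"
    evalue_factor: float = 1.0
    isotope_delta: float = 12.07532
    pair_rt_window: float | None = 120.0


def _linear_candidates(index: PeptideIndex, observed_mass: float,
                       tol_ppm: float) -> list[LinearCandidate]:
    lo = observed_mass * (1 - tol_ppm * 1e-6 * 1.01)
    hi = observed_mass * (1 + tol_ppm * 1e-6 * 1.01)
    out = []
    for mass, pep, _sites in index.range(lo, hi):
        if abs(mass - observed_mass) <= mass * tol_ppm * 1e-6:
            out.append(LinearCandidate(pep, mass))
    return out


def _all_candidates(index, mass, cfg, linear=False):
    cands: list = []
    for form in ("light", "heavy"):
        cands.extend(enumerate_candidates(index, mass, form,
                                          cfg.precursor_ppm, cfg.linker))
    if linear:
        cands.extend(_linear_candidates(index, mass, cfg.precursor_ppm))
    return cands


def _absolute_site(pep: Peptide, link_pos: int) -> int:
    return pep.start + link_pos - 1


def two_step_search(spectra, small_db, full_db,
                    config: SearchConfig | None = None):
    """Two-step cross-link identification.

    Step 1 scores each spectrum against cross-link candidates drawn from a
    small targeted database and keeps the best match when its E-value is at
    most ``config.e_max``.  Step 2 re-scores the spectrum against the whole
    proteome — cross-link pairs plus linear peptides at the same precursor
    mass — and the tentative hit is validated only if it remains
    top-ranked.  Scans whose winning candidate recurs in the other isotope
    form of a paired precursor are flagged ``paired``.

    ``small_db`` / ``full_db`` are lists of :class:`ProteinRecord`.
    Returns validated :class:`CrossLinkIdentification` records.
    """
    from .spectra import deconvolute, pair_precursors

    cfg = config or SearchConfig()
    if not small_db or not full_db:
        raise ValueError("both small_db and full_db are required")
    small_index = PeptideIndex.from_proteins(
        small_db, cfg.linker, cfg.max_missed, cfg.min_len, cfg.max_len)
    full_index = PeptideIndex.from_proteins(
        full_db, cfg.linker, cfg.max_missed, cfg.min_len, cfg.max_len)

    spectra = [s for s in spectra
               if s.precursor_charge <= cfg.max_precursor_charge]
    neutral = {s.scan_id: deconvolute(s) for s in spectra}

    # step 1: best small-database cross-link per spectrum
    tentative = {}
    for sp in spectra:
        peaks = neutral[sp.scan_id]
        cands = _all_candidates(small_index, peaks.precursor_neutral_mass, cfg)
        ranked = score_spectrum(peaks, cands, cfg.frag_tol)
        if ranked and ranked[0].e_value <= cfg.e_max:
            tentative[sp.scan_id] = ranked[0]

    # step 2: validation against the whole proteome
    validated = {}
    for sp in spectra:
        if sp.scan_id not in tentative:
            continue
        step1 = tentative[sp.scan_id]
        peaks = neutral[sp.scan_id]
        cands = _all_candidates(full_index, peaks.precursor_neutral_mass,
                                cfg, linear=True)
        ranked = score_spectrum(peaks, cands, cfg.frag_tol)
        if not ranked:
            continue
        best = ranked[0]
        same = best.candidate.key == step1.candidate.key
        if cfg.validation_mode == "top_ranked":
            ok = same
        else:  # evalue_factor: step-1 pair must score within a factor of the best
            rescored = next((r for r in ranked
                             if r.candidate.key == step1.candidate.key), None)
            ok = rescored is not None and (
                best.e_value == 0.0
                or rescored.e_value <= best.e_value * cfg.evalue_factor)
        if ok and not isinstance(step1.candidate, LinearCandidate):
            validated[sp.scan_id] = replace(step1)
        elif not same and sp.scan_id in tentative:
            pass  # displaced by a better whole-proteome explanation

    # isotope evidence
    pairs = pair_precursors(spectra, cfg.isotope_delta,
                            cfg.precursor_ppm, cfg.pair_rt_window)
    paired_scans = set()
    for light, heavy in pairs:
        a, b = validated.get(light.scan_id), validated.get(heavy.scan_id)
        if a is not None and b is not None and _pair_key(a) == _pair_key(b):
            paired_scans.update((light.scan_id, heavy.scan_id))

    out = []
    for scan_id in sorted(validated):
        m = validated[scan_id]
        c = m.candidate
        evidence = "paired" if scan_id in paired_scans else c.isotope_form
        out.append(CrossLinkIdentification(
            protein_a=c.peptide_alpha.protein_id,
            residue_a=_absolute_site(c.peptide_alpha, c.link_pos_alpha),
            protein_b=c.peptide_beta.protein_id,
            residue_b=_absolute_site(c.peptide_beta, c.link_pos_beta),
            peptide_a=c.peptide_alpha.sequence,
            peptide_b=c.peptide_beta.sequence,
            scan_id=scan_id,
            isotope_evidence=evidence,
            e_value=m.e_value,
            n_matched=m.n_matched,
            n_theoretical=m.n_theoretical,
        ))
    return out


def _pair_key(match: ScoredMatch):
    c = match.candidate
    return tuple(sorted([
        (c.peptide_alpha.protein_id, _absolute_site(c.peptide_alpha, c.link_pos_alpha)),
        (c.peptide_beta.protein_id, _absolute_site(c.peptide_beta, c.link_pos_beta)),
    ]))
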