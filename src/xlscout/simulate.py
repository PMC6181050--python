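"""Synthetic data with the statistical structure the pipelines assume.

Every generator is a pure function of its parameters and seed, and each
returns ground truth alongside the data so recall and precision can be
scored without re-reading the outputs.

* :func:`gen_proteome` — random protein databases with guaranteed linkable
  lysines.
* :func:`gen_spectra` — fragment spectra of planted cross-links: sampled
  b/y ions with Gaussian ppm mass error, uniform noise peaks, precursor
  charges 3-6, and optional heavy twins offset by the d12 tag
  (12.07532 Da).
* :func:`gen_gel_signals` — gel band tables where each band's signal is
  gain x sum(copies x carbons) x lognormal noise, mirroring uniform-label
  densitometry across three electrophoretic systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemistry import DSS, CrossLinkCandidate, CrossLinker, link_sites
from .proteome import ProteinRecord, carbon_count, digest
from .scoring import theoretical_fragments
from .spectra import Ms2Spectrum, mass_to_mz
from .stoichiometry import DEFAULT_ROUTES, GelBandMeasurement, GelRoutes

__all__ = [
    "PlantedLink",
    "SimulationTruth",
    "gen_proteome",
    "gen_spectra",
    "gen_gel_signals",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedLink:
    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    candidate: CrossLinkCandidate


@dataclass
class SimulationTruth:
    seed: int
    proteins: list = field(default_factory=list)
    links: list = field(default_factory=list)  # PlantedLink
    provenance: dict = field(default_factory=dict)  # scan_id -> PlantedLink | "noise"


def gen_proteome(n_proteins: int, length_range=(80, 120), seed: int = 0,
                 prefix: str = "SYN") -> list[ProteinRecord]:
    """Random proteins with uniform residue usage and >= 2 internal K each.

    Internal lysines guarantee linkable tryptic peptides.  Deterministic
    per seed.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = list(rng.choice(list(AMINO_ACIDS), size=length))
        internal = [j for j in range(1, length - 1) if seq[j] == "K"]
        while len(internal) < 2:
            j = int(rng.integers(1, length - 1))
            if seq[j] != "K":
                seq[j] = "K"
                internal.append(j)
        records.append(ProteinRecord(
            id=f"{prefix}{i + 1:04d}",
            description=f"{prefix}{i + 1:04d} synthetic protein",
            sequence="".join(seq)))
    return records


def _linkable_peptides(protein: ProteinRecord, linker: CrossLinker,
                       max_missed: int = 3, min_len: int = 4, max_len: int = 40):
    out = []
    for pep in digest(protein, max_missed=max_missed, min_len=min_len,
                      max_len=max_len):
        sites = link_sites(pep, linker, protein_length=len(protein))
        if sites:
            out.append((pep, sites))
    return out


def gen_spectra(
    proteins,
    n_links: int = 50,
    frag_fraction: float = 0.8,
    ppm_sigma: float = 5.0,
    n_noise_peaks: int = 10,
    isotope_pairing: bool = False,
    n_pure_noise: int = 0,
    seed: int = 0,
    linker: CrossLinker = DSS,
) -> tuple[list[Ms2Spectrum], SimulationTruth]:
    """Simulate MS2 spectra of planted cross-links.

    Per planted link a light spectrum is produced (plus a heavy twin at
    +12.07532 Da when ``isotope_pairing``): each theoretical fragment is
    retained with probability ``frag_fraction`` (at least one survivor),
    perturbed by Gaussian mass error of ``ppm_sigma``, and emitted at
    charge 1 m/z together with ``n_noise_peaks`` uniform noise peaks with
    exponential intensities.  ``n_pure_noise`` extra spectra contain noise
    only.  Precursor charges are drawn from 3-6.
    """
    if not 0 < frag_fraction <= 1:
        raise ValueError("frag_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed, proteins=list(proteins))

    pools = [(prot, _linkable_peptides(prot, linker)) for prot in proteins]
    pools = [(p, peps) for p, peps in pools if peps]
    if not pools:
        raise ValueError("no linkable peptides in the proteome")

    spectra: list[Ms2Spectrum] = []

    def emit(scan_id, cand, origin):
        precursor_charge = int(rng.integers(3, 7))
        frags = theoretical_fragments(cand)
        keep = rng.random(len(frags)) < frag_fraction
        if not keep.any():
            keep[int(rng.integers(0, len(frags)))] = True
        masses = np.array([f.neutral_mass for f in frags])[keep]
        masses = masses * (1.0 + rng.normal(0.0, ppm_sigma * 1e-6, masses.size))
        intens = rng.exponential(1000.0, masses.size) + 100.0
        mz = masses + 1.00727646  # fragments emitted singly charged
        prec_mass = cand.theoretical_neutral_mass * (
            1.0 + rng.normal(0.0, ppm_sigma * 1e-6))
        noise_mz = rng.uniform(100.0, max(200.0, prec_mass), n_noise_peaks) \
            + 1.00727646
        noise_int = rng.exponential(300.0, n_noise_peaks)
        peaks = list(zip(np.concatenate([mz, noise_mz]),
                         np.concatenate([intens, noise_int])))
        sp = Ms2Spectrum(
            scan_id=scan_id,
            precursor_mz=mass_to_mz(prec_mass, precursor_charge),
            precursor_charge=precursor_charge,
            peaks=peaks,
            retention_time=float(rng.uniform(0.0, 3600.0)))
        spectra.append(sp)
        truth.provenance[scan_id] = origin

    for k in range(n_links):
        ia = int(rng.integers(0, len(pools)))
        ib = int(rng.integers(0, len(pools)))
        prot_a, peps_a = pools[ia]
        prot_b, peps_b = pools[ib]
        pep_a, sites_a = peps_a[int(rng.integers(0, len(peps_a)))]
        pep_b, sites_b = peps_b[int(rng.integers(0, len(peps_b)))]
        sa = int(sites_a[int(rng.integers(0, len(sites_a)))])
        sb = int(sites_b[int(rng.integers(0, len(sites_b)))])
        for form in (("light", "heavy") if isotope_pairing else ("light",)):
            cand = CrossLinkCandidate(
                peptide_alpha=pep_a, peptide_beta=pep_b,
                link_pos_alpha=sa, link_pos_beta=sb,
                isotope_form=form,
                theoretical_neutral_mass=(pep_a.mass + pep_b.mass
                                          + linker.bridge_mass(form)),
                linker=linker)
            link = PlantedLink(pep_a.protein_id, pep_a.start + sa - 1,
                               pep_b.protein_id, pep_b.start + sb - 1, cand)
            if form == "light":
                truth.links.append(link)
            emit(f"planted_{k:04d}_{form}", cand, link)

    for k in range(n_pure_noise):
        precursor_charge = int(rng.integers(3, 7))
        prec_mass = float(rng.uniform(1500.0, 4000.0))
        n_pk = max(n_noise_peaks, 20)
        mzs = rng.uniform(100.0, prec_mass, n_pk) + 1.00727646
        ints = rng.exponential(300.0, n_pk)
        scan_id = f"noise_{k:04d}"
        spectra.append(Ms2Spectrum(
            scan_id=scan_id,
            precursor_mz=mass_to_mz(prec_mass, precursor_charge),
            precursor_charge=precursor_charge,
            peaks=list(zip(mzs, ints)),
            retention_time=float(rng.uniform(0.0, 3600.0))))
        truth.provenance[scan_id] = "noise"

    return spectra, truth


def gen_gel_signals(
    copy_numbers: dict,
    carbon_counts: dict,
    routes: GelRoutes = DEFAULT_ROUTES,
    n_replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[GelBandMeasurement]:
    """Simulate densitometry band tables for the three gel systems.

    Band signal = per-system gain x sum over members of copies x carbons,
    times lognormal noise of coefficient of variation ``noise_cv``.
    System gains are drawn log-uniformly so that absolute scales are
    meaningless, as on real film.
    """
    rng = np.random.default_rng(seed)
    bands_by_system = {
        routes.direct_system:
            [(s, frozenset({s})) for s in routes.direct_subunits],
        routes.calib_system:
            [("+".join(sorted(routes.calib_band)), routes.calib_band)]
            + [(s, frozenset({s})) for s in routes.calib_subunits],
        routes.partition_system:
            [(s, frozenset({s})) for s in routes.partition_subunits],
    }
    # composite bands of the direct system: each label "A/B" holds the two
    # named subunits (the second token is a shared comigrating partner)
    composite = {
        "LHCA7/2": frozenset({"LHCA7", "LHCA2"}),
        "LHCA8/2": frozenset({"LHCA8", "LHCA2"}),
    }
    for label in routes.partition_bands:
        bands_by_system[routes.direct_system].append((label, composite[label]))

    # LHCA2 splits its population across the two composite bands
    split_fraction = {"LHCA7/2": 0.5, "LHCA8/2": 0.5}

    out = []
    for rep in range(1, n_replicates + 1):
        gains = {sys_: float(10.0 ** rng.uniform(-1, 1))
                 for sys_ in bands_by_system}
        for sys_, bands in bands_by_system.items():
            for label, members in bands:
                expected = 0.0
                for s in members:
                    c = copy_numbers[s] * carbon_counts[s]
                    if label in split_fraction and s == "LHCA2":
                        c *= split_fraction[label]
                    expected += c
                if noise_cv > 0:
                    # lognormal with mean 1 and the requested CV
                    sigma = np.sqrt(np.log1p(noise_cv ** 2))
                    noise = float(rng.lognormal(-sigma ** 2 / 2.0, sigma))
                else:
                    noise = 1.0
                out.append(GelBandMeasurement(
                    gel_system=sys_, band_label=label, members=members,
                    signal=gains[sys_] * expected * noise, replicate=rep))
    return out
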