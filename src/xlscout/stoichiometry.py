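"""Densitometric subunit stoichiometry from uniformly 14C-labeled gels.

With uniform carbon labeling, a band's autoradiography signal is
proportional to (molar amount) x (carbon atoms per polypeptide), so
dividing each signal by the subunit's carbon number yields relative molar
amounts.  Three electrophoretic systems are combined:

* a high-temperature system resolving most subunits directly,
* a low-temperature system resolving subunits that comigrate above, put on
  the common scale through a comigrated calibration band whose expected
  total is known from the first system, and
* a 2D system whose spot pattern partitions composite bands into their
  members.

All outputs are normalized to a reference subunit (PSAF by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GelBandMeasurement",
    "SubunitAbundance",
    "GelRoutes",
    "DEFAULT_ROUTES",
    "molar_signal",
    "comigrated_band_molar",
    "calibrate_comigrated",
    "partition_composite",
    "integrate",
    "read_band_table",
]


@dataclass(frozen=True)
class GelBandMeasurement:
    """One densitometry reading: a band of one gel system in one replicate."""

    gel_system: str
    band_label: str
    members: frozenset
    signal: float
    replicate: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"band {self.band_label!r} has no members")
        if self.signal < 0:
            raise ValueError(f"negative signal for band {self.band_label!r}")


@dataclass(frozen=True)
class SubunitAbundance:
    subunit: str
    mean: float
    se: float
    n: int
    copies: int


def molar_signal(signal: float, carbon_count: int) -> float:
    """Relative molar amount: signal divided by the polypeptide's carbons."""
    if carbon_count <= 0:
        raise ValueError("carbon_count must be positive")
    return signal / carbon_count


def comigrated_band_molar(signal: float, member_copies, member_carbons) -> float:
    """Total molar value of a band holding several comigrating subunits.

    The band signal is split among members in proportion to their expected
    signal shares (reference copies x carbons, from a system where each
    member was resolved), then each share is carbon-normalized and the
    molar values summed.
    """
    weights = {s: member_copies[s] * member_carbons[s] for s in member_copies}
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ValueError("member copies/carbons must be positive")
    return sum(
        (signal * w / total_w) / member_carbons[s] for s, w in weights.items()
    )


def calibrate_comigrated(band_molar_value: float, reference_sum: float) -> float:
    """Scale factor putting one gel system on the reference system's scale.

    ``scale = reference_sum / band_molar_value`` where the band holds
    subunits whose summed molar amount is known to be ``reference_sum``
    from another system.
    """
    if band_molar_value <= 0:
        raise ValueError("comigrated band molar value must be positive")
    return reference_sum / band_molar_value


def partition_composite(total_molar: float, ratio_fractions) -> list[float]:
    """Split a composite molar total by molar fractions summing to one."""
    s = sum(ratio_fractions)
    if not math.isclose(s, 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions sum to {s}, expected 1")
    return [total_molar * f for f in ratio_fractions]


@dataclass(frozen=True)
class GelRoutes:
    """Which gel system resolves which subunit, mirroring the band map.

    * ``direct``: subunit -> system where it runs as a single band.
    * ``calibrated``: (system, calibration band members) and the subunits
      read from that system after calibration.
    * ``partition``: subunits quantified by splitting the listed composite
      bands of the direct system using a 2D system's spot fractions.
    """

    direct_system: str
    direct_subunits: tuple
    calib_system: str
    calib_band: frozenset
    calib_subunits: tuple
    partition_system: str
    partition_subunits: tuple
    partition_bands: tuple  # composite band labels in the direct system


# Band map of the study system: High-Molarity-Tris SDS-PAGE at 55C (HMT55)
# resolves LHCA4/6/3/5 and PSAD/PSAF; at 6C (HMT6) PSAD+PSAF comigrate and
# LHCA1/LHCA9 resolve; 2D (TWODIM) separates LHCA2/LHCA7/LHCA8.
DEFAULT_ROUTES = GelRoutes(
    direct_system="HMT55",
    direct_subunits=("LHCA4", "LHCA6", "LHCA3", "LHCA5", "PSAD", "PSAF"),
    calib_system="HMT6",
    calib_band=frozenset({"PSAD", "PSAF"}),
    calib_subunits=("LHCA1", "LHCA9"),
    partition_system="TWODIM",
    partition_subunits=("LHCA2", "LHCA7", "LHCA8"),
    partition_bands=("LHCA7/2", "LHCA8/2"),
)

LHCI_SUBUNITS = tuple(f"LHCA{i}" for i in range(1, 10))


def read_band_table(path) -> list[GelBandMeasurement]:
    """Read a TSV with columns gel_system, band_label, members, signal,
    replicate; ``members`` is a semicolon-separated subunit list."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gel_system", "band_label", "members", "signal", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    return [
        GelBandMeasurement(
            gel_system=str(r.gel_system),
            band_label=str(r.band_label),
            members=frozenset(str(r.members).split(";")),
            signal=float(r.signal),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def _round_copies(value: float) -> int:
    """Nearest integer, ties away from zero."""
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def integrate(
    bands,
    carbon_counts,
    reference: str = "PSAF",
    routes: GelRoutes = DEFAULT_ROUTES,
    warn_ambiguous=None,
) -> list[SubunitAbundance]:
    """Combine all gel systems and replicates into per-subunit copy numbers.

    Per replicate: (1) carbon-normalize the direct system's single bands;
    (2) calibrate the second system on its comigrated band and read the
    subunits it resolves; (3) partition the direct system's composite bands
    by the 2D spot fractions; (4) normalize to the reference subunit.
    Means and standard errors (sample sd / sqrt n) are taken across
    replicates.  ``warn_ambiguous`` (callable) is invoked for copy values
    whose fractional part falls in the ambiguity zone [0.4, 0.6].
    """
    by_rep: dict[int, list[GelBandMeasurement]] = {}
    for b in bands:
        by_rep.setdefault(b.replicate, []).append(b)

    all_subunits = (set(routes.direct_subunits) | set(routes.calib_subunits)
                    | set(routes.partition_subunits))
    per_rep_values: dict[str, list[float]] = {s: [] for s in all_subunits}

    for rep in sorted(by_rep):
        rbands = by_rep[rep]

        def find(system, predicate):
            hits = [b for b in rbands if b.gel_system == system and predicate(b)]
            return hits

        # 1) direct single-subunit bands
        values: dict[str, float] = {}
        for sub in routes.direct_subunits:
            hits = find(routes.direct_system,
                        lambda b, s=sub: b.members == frozenset({s}))
            if not hits:
                raise ValueError(
                    f"no resolution route for subunit {sub!r} "
                    f"(missing single band in {routes.direct_system}, replicate {rep})")
            values[sub] = molar_signal(sum(h.signal for h in hits),
                                       carbon_counts[sub])

        # 2) calibrated second system
        calib_hits = find(routes.calib_system,
                          lambda b: b.members == routes.calib_band)
        if not calib_hits:
            raise ValueError(
                f"calibration band {sorted(routes.calib_band)} absent from "
                f"{routes.calib_system}, replicate {rep}")
        ref_copies = {s: values[s] for s in routes.calib_band}
        band_molar = comigrated_band_molar(
            sum(h.signal for h in calib_hits), ref_copies,
            {s: carbon_counts[s] for s in routes.calib_band})
        scale = calibrate_comigrated(
            band_molar, sum(values[s] for s in routes.calib_band))
        for sub in routes.calib_subunits:
            hits = find(routes.calib_system,
                        lambda b, s=sub: b.members == frozenset({s}))
            if not hits:
                raise ValueError(
                    f"no resolution route for subunit {sub!r} "
                    f"(missing single band in {routes.calib_system}, replicate {rep})")
            values[sub] = scale * molar_signal(sum(h.signal for h in hits),
                                               carbon_counts[sub])

        # 3) composite-band partition via the 2D system
        spot = {}
        for sub in routes.partition_subunits:
            hits = find(routes.partition_system,
                        lambda b, s=sub: b.members == frozenset({s}))
            if not hits:
                raise ValueError(
                    f"no resolution route for subunit {sub!r} "
                    f"(missing spot in {routes.partition_system}, replicate {rep})")
            spot[sub] = sum(h.signal for h in hits)
        comp_hits = [b for b in rbands
                     if b.gel_system == routes.direct_system
                     and b.band_label in routes.partition_bands]
        if len({b.band_label for b in comp_hits}) != len(routes.partition_bands):
            raise ValueError(
                f"composite bands {routes.partition_bands} incomplete in "
                f"{routes.direct_system}, replicate {rep}")
        total_signal = sum(b.signal for b in comp_hits)
        # split the composite SIGNAL by raw 2D spot fractions, then
        # carbon-normalize: a band's raw signal is carbon-weighted
        spot_total = sum(spot.values())
        split_molar = {
            s: molar_signal(total_signal * spot[s] / spot_total,
                            carbon_counts[s])
            for s in routes.partition_subunits
        }
        total_molar = sum(split_molar.values())
        molar_fracs = [split_molar[s] / total_molar
                       for s in routes.partition_subunits]
        parts = partition_composite(total_molar, molar_fracs)
        for sub, v in zip(routes.partition_subunits, parts):
            values[sub] = v

        # 4) reference normalization
        ref = values[reference]
        for sub in all_subunits:
            per_rep_values[sub].append(values[sub] / ref)

    out = []
    for sub in sorted(all_subunits):
        vals = per_rep_values[sub]
        n = len(vals)
        mean = sum(vals) / n
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
            se = sd / math.sqrt(n)
        else:
            se = 0.0
        frac = mean - math.floor(mean)
        if 0.4 <= frac <= 0.6 and warn_ambiguous is not None:
            warn_ambiguous(sub, mean)
        out.append(SubunitAbundance(sub, mean, se, n, _round_copies(mean)))
    return out


def total_lhci_copies(abundances) -> int:
    return sum(a.copies for a in abundances if a.subunit in LHCI_SUBUNITS)


def abundance_table(abundances) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.subunit, a.mean, a.se, a.n, a.copies) for a in abundances],
        columns=["subunit", "mean_per_psaf", "se", "n_replicates", "copies"],
    )
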