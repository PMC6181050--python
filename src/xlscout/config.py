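"""Run configuration: plain key=value files, CLI overrides, provenance."""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, fields

__all__ = ["RunConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All defaults shared by the search, stoichiometry and topology tools.

    Tolerances follow data-dependent high-resolution acquisition practice:
    10 ppm for precursor ions, 0.05 Da or 10 ppm (whichever is wider) for
    product ions, precursor charges up to 6, Met oxidation as the only
    variable modification.
    """

    precursor_ppm: float = 10.0
    frag_da: float = 0.05
    frag_ppm: float = 10.0
    e_max: float = 0.01
    max_missed: int = 3
    min_len: int = 4
    max_len: int = 40
    max_precursor_charge: int = 6
    linker: str = "DSS"
    isotope_delta: float = 12.07532
    validation_mode: str = "top_ranked"
    evalue_factor: float = 1.0
    restraint_threshold: float = 30.0
    reference_subunit: str = "PSAF"
    seed: int = 0

    def to_search_config(self):
        from .chemistry import DSS
        from .scoring import FragTol, SearchConfig

        if self.linker != "DSS":
            raise ConfigError(f"unknown linker {self.linker!r}")
        return SearchConfig(
            precursor_ppm=self.precursor_ppm,
            frag_tol=FragTol(self.frag_da, self.frag_ppm),
            e_max=self.e_max,
            max_missed=self.max_missed,
            min_len=self.min_len,
            max_len=self.max_len,
            max_precursor_charge=self.max_precursor_charge,
            linker=DSS,
            validation_mode=self.validation_mode,
            evalue_factor=self.evalue_factor,
            isotope_delta=self.isotope_delta,
        )


def _coerce(name: str, raw: str, target_type):
    try:
        if target_type is bool:
            return raw.lower() in ("1", "true", "yes")
        return target_type(raw)
    except ValueError as exc:
        raise ConfigError(f"cannot parse value {raw!r} for key {name!r}") from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Resolve configuration: CLI overrides > file values > defaults."""
    known = {f.name: f.type for f in fields(RunConfig)}
    types = {f.name: type(getattr(RunConfig(), f.name)) for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected key=value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in known:
                    raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = _coerce(key, raw, types[key])
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
        values[key] = _coerce(key, str(val), types[key]) if isinstance(val, str) \
            else types[key](val)
    return RunConfig(**values)


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for key, val in asdict(cfg).items():
            fh.write(f"{key}={val}\n")


def provenance_header(cfg: RunConfig, inputs=()) -> list[str]:
    """'#'-prefixed header lines echoing the resolved configuration."""
    from . import __version__

    lines = [f"# xlscout {__version__}",
             f"# generated {time.strftime('%Y-%m-%dT%H:%M:%S')}"]
    for key, val in asdict(cfg).items():
        lines.append(f"# {key}={val}")
    for p in inputs:
        try:
            digest = hashlib.sha256(open(p, "rb").read()).hexdigest()[:16]
            lines.append(f"# input {p} sha256:{digest}")
        except OSError:
            lines.append(f"# input {p} (unreadable)")
    return lines
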