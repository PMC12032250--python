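"""Validated configuration files for the simulators.

Config files are YAML with a top-level ``kind`` (``cage`` or ``epi``) and
keys mirroring :class:`~drivesuite.cage.CageConfig` /
:class:`~drivesuite.epi.EpiConfig`.  Unknown keys are rejected with their
key path; probabilities are domain-checked by the underlying dataclasses.

Genotypes in founder censuses are written as strings like ``"D/W"`` (drive
locus only, effector wild type implied) or ``"D-C/W-E"`` (both loci,
hyphen-separated per haplotype).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Mapping, Union

import yaml

from .cage import CageConfig
from .epi import EpiConfig
from .genetics import (
    Diplotype,
    DriveAllele,
    DriveParams,
    EffectorAllele,
    FitnessClass,
    FitnessParams,
    Sex,
)

__all__ = ["load_config", "dump_config", "ConfigError", "parse_diplotype"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


_DRIVE_BY_NAME = {a.value: a for a in DriveAllele}
_EFFECTOR_BY_NAME = {a.value: a for a in EffectorAllele}


def parse_diplotype(text: str, sex: Sex) -> Diplotype:
    """Parse ``"D/W"`` or ``"D-C/W-E"`` into a :class:`Diplotype`."""
    haps = text.strip().split("/")
    if len(haps) != 2:
        raise ConfigError(f"genotype {text!r} must have two '/'-separated haplotypes")
    parsed = []
    for h in haps:
        parts = h.strip().split("-")
        if len(parts) == 1:
            d_name, e_name = parts[0], "C"
        elif len(parts) == 2:
            d_name, e_name = parts
        else:
            raise ConfigError(f"haplotype {h!r} in {text!r} is malformed")
        if d_name not in _DRIVE_BY_NAME:
            raise ConfigError(
                f"unknown drive allele {d_name!r} in {text!r} "
                f"(expected one of {sorted(_DRIVE_BY_NAME)})"
            )
        if e_name not in _EFFECTOR_BY_NAME:
            raise ConfigError(
                f"unknown effector allele {e_name!r} in {text!r} "
                f"(expected one of {sorted(_EFFECTOR_BY_NAME)})"
            )
        parsed.append((_DRIVE_BY_NAME[d_name], _EFFECTOR_BY_NAME[e_name]))
    return Diplotype(parsed[0], parsed[1], sex)


def _format_diplotype(d: Diplotype) -> str:
    return d.label()


def _reject_unknown(section: Mapping[str, Any], allowed, path: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} under {path!r}; "
            f"allowed: {sorted(allowed)}"
        )


def _build_drive(section: Mapping[str, Any], path: str) -> DriveParams:
    fields = {f.name for f in dataclasses.fields(DriveParams)}
    _reject_unknown(section, fields, path)
    try:
        return DriveParams(**section)
    except ValueError as e:
        raise ConfigError(f"{path}: {e}") from e


def _build_fitness(section: Mapping[str, Any], path: str) -> FitnessParams:
    allowed = {
        "daily_mort_mult_hom",
        "daily_mort_mult_het",
        "bloodmeal_mort_hom",
        "fecundity_mult",
        "mating_weight",
    }
    _reject_unknown(section, allowed, path)
    kwargs: Dict[str, Any] = dict(section)
    for name in ("fecundity_mult", "mating_weight"):
        if name in kwargs:
            by_class = {}
            for key, val in dict(kwargs[name]).items():
                try:
                    cls = FitnessClass(key)
                except ValueError:
                    raise ConfigError(
                        f"{path}.{name}: unknown fitness class {key!r} "
                        f"(expected one of {[c.value for c in FitnessClass]})"
                    )
                by_class[cls] = float(val)
            for cls in FitnessClass:
                by_class.setdefault(cls, 1.0)
            kwargs[name] = by_class
    try:
        return FitnessParams(**kwargs)
    except ValueError as e:
        raise ConfigError(f"{path}: {e}") from e


def _build_founders(section: Mapping[str, Any], path: str) -> Dict[Diplotype, int]:
    founders: Dict[Diplotype, int] = {}
    for geno, by_sex in section.items():
        if not isinstance(by_sex, Mapping):
            raise ConfigError(
                f"{path}.{geno}: expected a mapping of sex -> count"
            )
        _reject_unknown(by_sex, {"female", "male"}, f"{path}.{geno}")
        for sex_name, n in by_sex.items():
            if int(n) < 0:
                raise ConfigError(f"{path}.{geno}.{sex_name}: count must be >= 0")
            dip = parse_diplotype(str(geno), Sex(sex_name))
            founders[dip] = founders.get(dip, 0) + int(n)
    if not founders or sum(founders.values()) == 0:
        raise ConfigError(f"{path}: founder census is empty")
    return founders


def _build_cage(doc: Mapping[str, Any]) -> CageConfig:
    fields = {f.name for f in dataclasses.fields(CageConfig)}
    _reject_unknown(doc, fields | {"kind"}, "<root>")
    kwargs: Dict[str, Any] = {k: v for k, v in doc.items() if k != "kind"}
    if "founders" in kwargs:
        kwargs["founders"] = _build_founders(kwargs["founders"], "founders")
    if "drive" in kwargs:
        kwargs["drive"] = _build_drive(kwargs["drive"], "drive")
    if "fitness" in kwargs:
        kwargs["fitness"] = _build_fitness(kwargs["fitness"], "fitness")
    try:
        return CageConfig(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(str(e)) from e


def _build_epi(doc: Mapping[str, Any]) -> EpiConfig:
    fields = {f.name for f in dataclasses.fields(EpiConfig)}
    _reject_unknown(doc, fields | {"kind"}, "<root>")
    kwargs: Dict[str, Any] = {k: v for k, v in doc.items() if k != "kind"}
    if "drive" in kwargs:
        kwargs["drive"] = _build_drive(kwargs["drive"], "drive")
    if "fitness" in kwargs:
        kwargs["fitness"] = _build_fitness(kwargs["fitness"], "fitness")
    try:
        return EpiConfig(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(str(e)) from e


def load_config(path: Union[str, Path]) -> Union[CageConfig, EpiConfig]:
    """Load and validate a YAML config file.

    The file must declare ``kind: cage`` or ``kind: epi``; defaults are
    filled for omitted keys (e.g. ``cycle_days: 3``), unknown keys are
    rejected, and out-of-domain values are reported with their key path.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if doc is None:
        raise ConfigError(
            "empty config file; required: 'kind' (cage|epi) plus any "
            "fields to override"
        )
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    kind = doc.get("kind")
    if kind == "cage":
        return _build_cage(doc)
    if kind == "epi":
        return _build_epi(doc)
    raise ConfigError(f"config 'kind' must be 'cage' or 'epi', got {kind!r}")


def dump_config(config: Union[CageConfig, EpiConfig]) -> Dict[str, Any]:
    """Serialise a config back to a plain YAML-safe dict (round-trips
    through :func:`load_config`)."""
    if isinstance(config, CageConfig):
        kind = "cage"
    elif isinstance(config, EpiConfig):
        kind = "epi"
    else:  # pragma: no cover - defensive
        raise TypeError(f"not a config object: {type(config)!r}")
    out: Dict[str, Any] = {"kind": kind}
    for f in dataclasses.fields(config):
        val = getattr(config, f.name)
        if f.name == "founders":
            founders: Dict[str, Dict[str, int]] = {}
            for dip, n in val.items():
                entry = founders.setdefault(_format_diplotype(dip), {})
                entry[dip.sex.value] = entry.get(dip.sex.value, 0) + int(n)
            out["founders"] = founders
        elif isinstance(val, DriveParams):
            out[f.name] = dataclasses.asdict(val)
        elif isinstance(val, FitnessParams):
            d = dataclasses.asdict(val)
            for name in ("fecundity_mult", "mating_weight"):
                d[name] = {cls.value: w for cls, w in d[name].items()}
            out[f.name] = d
        else:
            out[f.name] = val
    return out
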