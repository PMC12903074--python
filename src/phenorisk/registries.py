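"""Packaged parameter registries and their validation.

Ships the toxicity-endpoint table (per analyte x trophic level x class,
with assessment factors applied downstream), the age-group exposure
parameters and per-analyte reference doses, and the analytical QC limits
(LOD/LOQ/MDL per analyte), all as plain-text files under
``phenorisk/data``. Loaders return ordinary pandas/dataclass objects so a
user can substitute their own registries with the same schema.
"""

from __future__ import annotations

import importlib.resources as resources
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .ecorisk import ToxicityRecord
from .healthrisk import ExposureProfile, ReferenceDose

__all__ = [
    "load_toxicity_records",
    "load_exposure_profiles",
    "load_reference_doses",
    "load_qc_limits",
    "load_spe_volumes",
    "spe_enrichment_factor",
    "exposure_frequency",
    "RegistryError",
    "validate_registries",
]


class RegistryError(ValueError):
    """Registry fails schema validation."""


def _data_path(name: str):
    return resources.files("phenorisk.data").joinpath(name)


def load_toxicity_records(path=None) -> list[ToxicityRecord]:
    """Toxicity endpoints as a list of :class:`ToxicityRecord`.

    The packaged registry resolves range endpoints to their lower bound and
    inequality endpoints to the stated bound; the ``qualifier`` column
    records which rows were resolved that way.
    """
    src = path if path is not None else _data_path("toxicity_endpoints.csv")
    df = pd.read_csv(src)
    records = []
    for row in df.to_dict("records"):
        qual = row.get("qualifier")
        records.append(
            ToxicityRecord(
                analyte=row["analyte"],
                trophic_level=row["trophic_level"],
                endpoint=row["endpoint"],
                value=float(row["value_mg_L"]),
                toxicity_class=row["class"],
                qualifier=None if pd.isna(qual) or qual == "" else str(qual),
            )
        )
    return records


def _exposure_yaml(path=None) -> dict:
    src = path if path is not None else _data_path("exposure_parameters.yaml")
    with open(src) if isinstance(src, str) else src.open() as fh:
        return yaml.safe_load(fh)


def load_exposure_profiles(path=None) -> list[ExposureProfile]:
    doc = _exposure_yaml(path)
    profiles = []
    for group, p in doc["profiles"].items():
        profiles.append(
            ExposureProfile(
                group=group,
                dwi=float(p["dwi_L_per_day"]),
                bw=float(p["bw_kg"]),
                ab=float(p["ab"]),
                foe=float(p["foe_days_per_year"]) / 365.0,
            )
        )
    return profiles


def load_reference_doses(path=None) -> list[ReferenceDose]:
    doc = _exposure_yaml(path)
    return [
        ReferenceDose(
            analyte=analyte,
            kind=entry["kind"],
            value=float(entry["value_mg_per_kg_day"]),
            provisional=bool(entry.get("provisional", False)),
        )
        for analyte, entry in doc["reference_doses"].items()
    ]


def load_qc_limits(path=None) -> pd.DataFrame:
    src = path if path is not None else _data_path("qc_limits.csv")
    return pd.read_csv(src)


def load_spe_volumes(path=None) -> tuple[float, float]:
    doc = _exposure_yaml(path)
    spe = doc["spe"]
    return float(spe["sample_volume_mL"]), float(spe["reconstitution_volume_mL"])


def spe_enrichment_factor(path=None) -> float:
    """Pre-concentration factor of the extraction step: processed sample
    volume over reconstitution volume (250 mL / 0.5 mL = 500)."""
    sample, recon = load_spe_volumes(path)
    if recon <= 0:
        raise RegistryError("reconstitution volume must be > 0")
    return sample / recon


def exposure_frequency(path=None) -> float:
    """Exposure-frequency fraction FOE shared by all profiles (350/365)."""
    doc = _exposure_yaml(path)
    days = {float(p["foe_days_per_year"]) for p in doc["profiles"].values()}
    if len(days) != 1:
        raise RegistryError("profiles disagree on exposure days per year")
    return days.pop() / 365.0


def validate_registries(
    toxicity: Iterable[ToxicityRecord],
    profiles: Sequence[ExposureProfile],
    reference_doses: Sequence[ReferenceDose],
    analytes: Sequence[str] = (),
) -> list[str]:
    """Cross-check the three registries; returns coverage warnings.

    Schema violations (duplicate keys, nonpositive values — already
    enforced by the dataclasses) raise :class:`RegistryError`; an analyte
    present in the data but missing registry rows produces a warning so the
    pipeline can skip it explicitly rather than fail.
    """
    warnings: list[str] = []
    tox = list(toxicity)
    keys = [(r.analyte, r.trophic_level, r.toxicity_class) for r in tox]
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise RegistryError(f"duplicate toxicity keys: {dupes}")
    if not profiles:
        raise RegistryError("no exposure profiles")
    groups = [p.group for p in profiles]
    if len(groups) != len(set(groups)):
        raise RegistryError("duplicate exposure-profile groups")
    rfd_analytes = [r.analyte for r in reference_doses]
    if len(rfd_analytes) != len(set(rfd_analytes)):
        raise RegistryError("duplicate reference-dose analytes")

    tox_analytes = {r.analyte for r in tox}
    for a in analytes:
        if a not in tox_analytes:
            warnings.append(f"analyte {a!r} has no toxicity endpoints; eco-risk skipped")
        else:
            have = {(r.trophic_level, r.toxicity_class) for r in tox if r.analyte == a}
            for trophic in ("algae", "invertebrate", "fish"):
                for cls in ("acute", "chronic"):
                    if (trophic, cls) not in have:
                        warnings.append(
                            f"analyte {a!r}: no {cls} endpoint for {trophic}; "
                            "that quotient is omitted"
                        )
        if a not in set(rfd_analytes):
            warnings.append(f"analyte {a!r} has no reference dose; health risk skipped")
    return warnings
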