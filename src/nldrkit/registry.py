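"""Canonical variable registry for donor cohort tables.

The assessment system works on one target variable (operative time, in
minutes) and 16 candidate predictors describing the donor's physique,
serum metabolites and perinephric / subcutaneous anatomy measured on a
cross-sectional abdominal CT slice.  Every module addresses variables by
the canonical snake_case names defined here; reader code resolves the
short clinical aliases (``Bw``, ``numberRA``, ``areaPNF`` ...) commonly
used in published tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass(frozen=True)
class VariableSpec:
    """One variable of the cohort table.

    Parameters
    ----------
    name : canonical snake_case identifier.
    unit : measurement unit as printed in clinical tables.
    kind : ``continuous``, ``binary`` or ``ordinal-count``.
    aliases : alternative column headers accepted by the reader.
    """

    name: str
    unit: str
    kind: str
    aliases: tuple[str, ...] = field(default_factory=tuple)


TARGET = VariableSpec(
    "operative_time", "min", "continuous",
    ("operative time", "optime", "OPtime", "op_time", "OperativeTime",
     "operative time (min)", "time"),
)

#: The 16 candidate predictors, in canonical order.  This order defines the
#: bit positions of subset masks everywhere in the package (bit 0 = sex_male).
PREDICTORS: tuple[VariableSpec, ...] = (
    VariableSpec("sex_male", "1=male/0=female", "binary",
                 ("sex", "male", "sexmale", "gender", "Male / Female (1/0)")),
    VariableSpec("age", "years", "continuous", ("Age",)),
    VariableSpec("body_weight", "kg", "continuous",
                 ("Bw", "bodyweight", "weight", "Body weight (kg)")),
    VariableSpec("body_height", "cm", "continuous",
                 ("Ht", "bodyheight", "height", "Body height (cm)")),
    VariableSpec("total_protein", "g/dL", "continuous",
                 ("TP", "totalprotein", "Total protein (g/dL)")),
    VariableSpec("albumin", "g/dL", "continuous",
                 ("Alb", "Albumin (g/dL)")),
    VariableSpec("triglyceride", "mg/dL", "continuous",
                 ("TG", "Triglyceride (mg/dL)")),
    VariableSpec("total_cholesterol", "mg/dL", "continuous",
                 ("TC", "totalcholesterol", "Total cholesterol (mg/dL)")),
    VariableSpec("number_ra", "count", "ordinal-count",
                 ("numberRA", "nRA", "renal_arteries")),
    VariableSpec("maxthick_mpf", "mm", "continuous",
                 ("maxthickMPF", "maxthickMPF (mm)")),
    VariableSpec("medthick_mpf", "mm", "continuous",
                 ("medthickMPF", "medthickMPF (mm)")),
    VariableSpec("medthick_lpf", "mm", "continuous",
                 ("medthickLPF", "medthickLPF (mm)")),
    VariableSpec("area_pnf", "cm^2", "continuous",
                 ("areaPNF", "areaPNF (cm2)")),
    VariableSpec("ctv_pnf", "CT value (HU-like)", "continuous",
                 ("ctvPNF",)),
    VariableSpec("thick_scf", "mm", "continuous",
                 ("thickSCF", "thickSCF (mm)")),
    VariableSpec("area_scf", "cm^2", "continuous",
                 ("areaSCF", "areaSCF (cm2)")),
)

PREDICTOR_NAMES: tuple[str, ...] = tuple(v.name for v in PREDICTORS)
ALL_SPECS: tuple[VariableSpec, ...] = (TARGET,) + PREDICTORS

#: Optional per-record column: surgical complication grade (modified Clavien
#: scale for donor nephrectomy), encoded as an ordered rank for rank
#: correlations.  Grade 0 means no complication.
COMPLICATION_COLUMN = "complication_grade"
CLAVIEN_RANKS: dict[str, int] = {
    "0": 0, "1": 1, "2a": 2, "2b": 3, "3a": 4, "3b": 5, "4a": 6, "4b": 7,
}

# Named predictor subsets used in the study's model-building sequence:
# A = physique, B = A + serum metabolites, C = B + perinephric CT anatomy,
# D = C + subcutaneous fat, E = the 9-variable model selected by the
# exhaustive-search / cross-validation / .632 funnel.
NAMED_SETS: dict[str, tuple[str, ...]] = {
    "A": ("sex_male", "age", "body_weight", "body_height"),
    "B": ("sex_male", "age", "body_weight", "body_height",
          "total_protein", "albumin", "triglyceride", "total_cholesterol"),
    "C": ("sex_male", "age", "body_weight", "body_height",
          "total_protein", "albumin", "triglyceride", "total_cholesterol",
          "number_ra", "maxthick_mpf", "medthick_mpf", "medthick_lpf",
          "area_pnf", "ctv_pnf"),
    "D": PREDICTOR_NAMES,
    "E": ("age", "total_protein", "total_cholesterol", "number_ra",
          "maxthick_mpf", "medthick_mpf", "area_pnf", "ctv_pnf", "area_scf"),
}


def _norm(header: str) -> str:
    """Normalise a column header for alias matching."""
    return re.sub(r"[^a-z0-9]", "", header.lower())


def _build_alias_index() -> dict[str, str]:
    index: dict[str, str] = {}
    for spec in ALL_SPECS:
        index[_norm(spec.name)] = spec.name
        for alias in spec.aliases:
            index.setdefault(_norm(alias), spec.name)
    return index


_ALIAS_INDEX = _build_alias_index()


def resolve_column(header: str, extra_aliases: dict[str, str] | None = None) -> str | None:
    """Map a source column header to its canonical name, or None."""
    if extra_aliases:
        for alias, canonical in extra_aliases.items():
            if _norm(alias) == _norm(header):
                return canonical
    return _ALIAS_INDEX.get(_norm(header))


def names_to_mask(names) -> int:
    """Encode a predictor subset as a 16-bit mask over the canonical order."""
    mask = 0
    for name in names:
        try:
            mask |= 1 << PREDICTOR_NAMES.index(name)
        except ValueError:
            raise KeyError(f"unknown predictor: {name!r}") from None
    return mask


def mask_to_names(mask: int) -> tuple[str, ...]:
    """Decode a subset mask back to canonical predictor names."""
    if not 0 < mask < (1 << len(PREDICTORS)):
        raise ValueError(f"mask out of range: {mask}")
    return tuple(n for i, n in enumerate(PREDICTOR_NAMES) if mask >> i & 1)
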