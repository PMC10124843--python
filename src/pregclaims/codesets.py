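"""Curated code lists that drive every classification step.

A code set is a validated table of diagnosis, procedure, and DRG codes, each
carrying a *category* (what role the code plays in the algorithm), an
optional *outcome class* (live birth, stillbirth, spontaneous/induced
abortion, ectopic, unknown), and an optional assigned gestational age in
completed weeks.  Direct gestational-age codes (ICD-10-CM ``Z3A.NN``,
ICD-9-CM ``765.2X``) always carry an assigned week.

The package ships a documented fixture subset of well-known codes
(:func:`default_codeset`); production users supply their own curated list in
the same comma-separated schema.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

SYSTEMS = frozenset(
    {"ICD9-DX", "ICD10-DX", "ICD9-PX", "ICD10-PX", "CPT", "HCPCS", "DRG"}
)
CATEGORIES = frozenset(
    {
        "outcome",
        "direct_gestational_age",
        "infant_birth_hospitalization",
        "preterm_prolonged",
        "ectopic_verification",
        "methotrexate",
        "fertility_procedure",
    }
)
OUTCOME_CLASSES = frozenset({"LB", "SB", "LB_SB", "SAB", "IAB", "ECT", "UNKNOWN"})

#: Outcome classes the downstream hierarchy consumes; a production code set
#: must provide at least one outcome entry for each.
REQUIRED_OUTCOME_CLASSES = frozenset({"LB", "SB", "LB_SB", "SAB", "IAB", "ECT"})

COLUMNS = ["code", "system", "category", "outcome_class", "ga_weeks", "description"]

#: system -> broad code type used by the outcome hierarchy
CODE_TYPE_BY_SYSTEM = {
    "ICD9-DX": "DX",
    "ICD10-DX": "DX",
    "ICD9-PX": "PX",
    "ICD10-PX": "PX",
    "CPT": "PX",
    "HCPCS": "PX",
    "DRG": "DRG",
}

#: system -> coding-era version
CODE_VERSION_BY_SYSTEM = {
    "ICD9-DX": "ICD9",
    "ICD10-DX": "ICD10",
    "ICD9-PX": "ICD9",
    "ICD10-PX": "ICD10",
    "CPT": "other",
    "HCPCS": "other",
    "DRG": "other",
}


class CodeSetError(ValueError):
    """Raised when a code list fails schema or invariant validation."""


@dataclass(frozen=True)
class CodeEntry:
    """One curated code with the role(s) it plays in the algorithm."""

    code: str
    system: str
    category: str
    outcome_class: Optional[str] = None
    ga_weeks: Optional[int] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise CodeSetError(f"unknown code system {self.system!r} for {self.code!r}")
        if self.category not in CATEGORIES:
            raise CodeSetError(f"unknown category {self.category!r} for {self.code!r}")
        if self.outcome_class is not None and self.outcome_class not in OUTCOME_CLASSES:
            raise CodeSetError(
                f"unknown outcome class {self.outcome_class!r} for {self.code!r}"
            )
        if self.category == "outcome" and self.outcome_class is None:
            raise CodeSetError(f"outcome entry {self.code!r} lacks an outcome class")
        if self.category == "direct_gestational_age":
            if self.ga_weeks is None:
                raise CodeSetError(
                    f"direct gestational-age entry {self.code!r} lacks ga_weeks"
                )
            if not 1 <= self.ga_weeks <= 45:
                raise CodeSetError(
                    f"ga_weeks {self.ga_weeks} out of range [1, 45] for {self.code!r}"
                )


@dataclass
class CodeSet:
    """Validated collection of :class:`CodeEntry` with (code, system) lookup."""

    entries: list[CodeEntry]
    provenance: str = ""
    _index: dict[tuple[str, str], list[CodeEntry]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str, str], CodeEntry] = {}
        dups = []
        for e in self.entries:
            key = (e.code, e.system, e.category)
            if key in seen:
                dups.append(key)
            seen[key] = e
            self._index.setdefault((e.code, e.system), []).append(e)
        if dups:
            raise CodeSetError(f"duplicate (code, system, category) rows: {sorted(dups)}")

    def classify(self, code: str, system: str) -> list[tuple[str, Optional[str], Optional[int]]]:
        """All roles a code plays: ``(category, outcome_class, ga_weeks)`` tuples.

        Codes absent from the set return an empty list; the corresponding
        claim is simply ignored downstream.  Matching is exact-string after
        trimming and uppercasing — wildcard families must be expanded in the
        input file.
        """
        key = (str(code).strip().upper(), system)
        return [(e.category, e.outcome_class, e.ga_weeks) for e in self._index.get(key, [])]

    def outcome_classes_present(self) -> frozenset[str]:
        return frozenset(
            e.outcome_class
            for e in self.entries
            if e.category == "outcome" and e.outcome_class is not None
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "code": e.code,
                "system": e.system,
                "category": e.category,
                "outcome_class": e.outcome_class or "",
                "ga_weeks": "" if e.ga_weeks is None else str(e.ga_weeks),
                "description": e.description,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows, columns=COLUMNS)

    def without_direct_ga(self) -> "CodeSet":
        """Copy of this set with direct gestational-age entries masked.

        Used by the sensitivity analysis that re-estimates gestational age
        from outcome codes alone.
        """
        kept = [e for e in self.entries if e.category != "direct_gestational_age"]
        return CodeSet(entries=kept, provenance=self.provenance + " [direct GA masked]")


def _parse_row(row: pd.Series, lineno: int) -> CodeEntry:
    code = str(row["code"]).strip().upper()
    if not code:
        raise CodeSetError(f"row {lineno}: empty code")
    oc = str(row["outcome_class"]).strip() or None
    ga_raw = str(row["ga_weeks"]).strip()
    if ga_raw:
        try:
            ga: Optional[int] = int(ga_raw)
        except ValueError as exc:
            raise CodeSetError(f"row {lineno}: ga_weeks {ga_raw!r} is not an integer") from exc
    else:
        ga = None
    try:
        return CodeEntry(
            code=code,
            system=str(row["system"]).strip(),
            category=str(row["category"]).strip(),
            outcome_class=oc,
            ga_weeks=ga,
            description=str(row["description"]).strip(),
        )
    except CodeSetError as exc:
        raise CodeSetError(f"row {lineno}: {exc}") from exc


def load_codeset(
    path: str | Path | io.IOBase,
    provenance: str | None = None,
    required_outcome_classes: Iterable[str] = REQUIRED_OUTCOME_CLASSES,
) -> CodeSet:
    """Load and validate a code list from a comma-separated file.

    The header row must be exactly ``code, system, category, outcome_class,
    ga_weeks, description``; empty strings mark absent outcome_class and
    ga_weeks.  Validation enforces the entry invariants, rejects duplicate
    (code, system, category) rows, and requires at least one outcome entry
    per outcome class in ``required_outcome_classes`` (pass an empty iterable
    to skip that check for partial lists).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CodeSetError(f"code list is missing required column(s): {missing}")
    entries = [_parse_row(row, i + 2) for i, (_, row) in enumerate(df.iterrows())]
    if provenance is None:
        provenance = str(getattr(path, "name", path))
    cs = CodeSet(entries=entries, provenance=provenance)
    needed = frozenset(required_outcome_classes) - cs.outcome_classes_present()
    if needed:
        raise CodeSetError(
            "code list has no outcome entry for required outcome class(es): "
            f"{sorted(needed)}"
        )
    return cs


def write_codeset(code_set: CodeSet, path: str | Path) -> None:
    code_set.to_frame().to_csv(path, index=False)


def classify_code(
    code_set: CodeSet, code: str, system: str
) -> list[tuple[str, Optional[str], Optional[int]]]:
    """Pure lookup of every role ``(category, outcome_class, ga_weeks)`` a
    code plays in ``code_set``; empty list for unknown codes."""
    return code_set.classify(code, system)


def default_codeset() -> CodeSet:
    """The bundled fixture code list (a documented subset, not a licensed
    production list)."""
    ref = resources.files("pregclaims.data").joinpath("default_codes.csv")
    with resources.as_file(ref) as p:
        return load_codeset(p, provenance="pregclaims bundled fixture code list")
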