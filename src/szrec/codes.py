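"""Named code sets and prefix matching for ICD-9/ICD-10/CPT dialects.

Codes are normalized by stripping dots and uppercasing, so the wildcard
notation common in phenotyping definitions ("345.**" for any ICD-9 code
starting 345, "G40.*" for any ICD-10 code starting G40) becomes plain prefix
matching on normalized strings.  Every prefix carries a dialect tag: "345"
as an ICD-9 prefix never matches an ICD-10 code.

The registry shipped by :func:`default_registry` is a documented default; the
study-grade supplementary code lists are pluggable via YAML
(:meth:`CodeSetRegistry.from_yaml`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError
from .records import DiagnosisCode


def normalize_code(code: str) -> str:
    return code.replace(".", "").upper()


@dataclass(frozen=True)
class AsmEntry:
    """One antiseizure-medication lexicon entry."""

    drug: str
    drug_class: str
    adjunctive: bool = False


@dataclass
class CodeSetRegistry:
    """Named sets of (normalized prefix, dialect) pairs plus the ASM lexicon.

    ``asm_lexicon`` maps normalized drug name -> AsmEntry; ``asm_aliases``
    maps surface abbreviations/brand names (e.g. "lev") to the normalized
    drug name.
    """

    sets: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    asm_lexicon: dict[str, AsmEntry] = field(default_factory=dict)
    asm_aliases: dict[str, str] = field(default_factory=dict)

    REQUIRED = (
        "seizure_like_broad",
        "epilepsy_specific",
        "convulsion_excluded",
        "status_epilepticus",
        "seizure_related_utilisation",
        "diagnostic_testing",
        "epilepsy_procedures",
    )

    def __post_init__(self):
        normalized: dict[str, list[tuple[str, str]]] = {}
        for name, prefixes in self.sets.items():
            normalized[name] = [
                (normalize_code(p), d) for p, d in prefixes
            ]
        self.sets = normalized
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        # Epilepsy-specific and convulsion prefixes must not overlap: one
        # being a prefix of the other (same dialect) would make the
        # "excluding convulsions" clause ambiguous.
        spec = self.sets.get("epilepsy_specific", [])
        conv = self.sets.get("convulsion_excluded", [])
        for p1, d1 in spec:
            for p2, d2 in conv:
                if d1 == d2 and (p1.startswith(p2) or p2.startswith(p1)):
                    raise ConfigurationError(
                        "epilepsy_specific and convulsion_excluded overlap: "
                        f"{p1}/{d1} vs {p2}/{d2}"
                    )

    def matches(self, set_name: str, code: str, dialect: str) -> bool:
        if set_name not in self.sets:
            raise ConfigurationError(f"unknown code set {set_name!r}")
        norm = normalize_code(code)
        return any(
            d == dialect and norm.startswith(prefix)
            for prefix, d in self.sets[set_name]
        )

    def code_matches(self, set_name: str, code: DiagnosisCode) -> bool:
        return self.matches(set_name, code.code, code.dialect)

    def encounter_matches(self, set_name: str, encounter) -> bool:
        return any(self.code_matches(set_name, c) for c in encounter.codes)

    def resolve_drug(self, surface: str) -> str | None:
        """Normalize a drug surface form via the alias table; None if unknown."""
        key = surface.lower().strip(".,;:")
        if key in self.asm_lexicon:
            return key
        return self.asm_aliases.get(key)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            "sets": {
                name: [[p, d] for p, d in prefixes]
                for name, prefixes in self.sets.items()
            },
            "asm_lexicon": {
                name: {
                    "class": e.drug_class,
                    "adjunctive": e.adjunctive,
                }
                for name, e in self.asm_lexicon.items()
            },
            "asm_aliases": dict(self.asm_aliases),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CodeSetRegistry":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        sets = {
            name: [(p, d) for p, d in prefixes]
            for name, prefixes in data.get("sets", {}).items()
        }
        lex = {
            name: AsmEntry(name, entry["class"], bool(entry.get("adjunctive")))
            for name, entry in data.get("asm_lexicon", {}).items()
        }
        return cls(sets=sets, asm_lexicon=lex,
                   asm_aliases=dict(data.get("asm_aliases", {})))


def default_registry() -> CodeSetRegistry:
    """Registry with genuine ICD-9/ICD-10 prefixes for the seizure code sets.

    The broad index-event definition covers epilepsy (345.*, G40.*) plus
    convulsions (780.3*, R56.*); the strict outcome definition is 345.*/G40.*
    only, explicitly excluding the convulsion families 780.* and R56.*.
    """
    sets = {
        "seizure_like_broad": [
            ("345", "icd9"), ("G40", "icd10"),
            ("7803", "icd9"), ("R56", "icd10"),
        ],
        "epilepsy_specific": [("345", "icd9"), ("G40", "icd10")],
        "convulsion_excluded": [("780", "icd9"), ("R56", "icd10")],
        "status_epilepticus": [
            ("3453", "icd9"),      # 345.3 grand mal status
            ("G40901", "icd10"), ("G40911", "icd10"),
            ("G40401", "icd10"), ("G40411", "icd10"),
        ],
        # Broader than epilepsy_specific: utilisation counts convulsions too.
        "seizure_related_utilisation": [
            ("345", "icd9"), ("G40", "icd10"),
            ("7803", "icd9"), ("R56", "icd10"),
        ],
        "diagnostic_testing": [
            ("95819", "cpt"), ("95816", "cpt"),  # EEG
            ("70551", "cpt"),                    # brain MRI
            ("70450", "cpt"),                    # head CT
        ],
        "epilepsy_procedures": [
            ("957", "cpt"),     # long-term EEG monitoring family
            ("61533", "cpt"),   # subdural electrode implantation
        ],
    }
    asm = {
        "levetiracetam": AsmEntry("levetiracetam", "asm", False),
        "oxcarbazepine": AsmEntry("oxcarbazepine", "asm", False),
        "lamotrigine": AsmEntry("lamotrigine", "asm", False),
        "valproate": AsmEntry("valproate", "asm", False),
        "topiramate": AsmEntry("topiramate", "asm", False),
        "ethosuximide": AsmEntry("ethosuximide", "asm", False),
        "phenobarbital": AsmEntry("phenobarbital", "asm", False),
        "carbamazepine": AsmEntry("carbamazepine", "asm", False),
        "zonisamide": AsmEntry("zonisamide", "asm", False),
        "clobazam": AsmEntry("clobazam", "asm", True),
        "lacosamide": AsmEntry("lacosamide", "asm", True),
        "perampanel": AsmEntry("perampanel", "asm", True),
        "gabapentin": AsmEntry("gabapentin", "asm", True),
    }
    aliases = {
        "lev": "levetiracetam",
        "keppra": "levetiracetam",
        "levetiracetam": "levetiracetam",
        "vpa": "valproate",
        "depakote": "valproate",
        "oxc": "oxcarbazepine",
        "ltg": "lamotrigine",
        "pb": "phenobarbital",
        "cbz": "carbamazepine",
    }
    aliases.update({name: name for name in asm})
    return CodeSetRegistry(sets=sets, asm_lexicon=asm, asm_aliases=aliases)
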