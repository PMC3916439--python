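"""Code dictionaries: NDC/procedure drug classes and ICD-9-CM prefix sets.

All ICD-9 matching in the package is prefix matching on the dot-stripped
code (``"493"`` matches ``"49390"`` and ``"493.90"``), because claims
extracts vary in decimal formatting. Drug classification is an exact lookup
of the NDC or procedure code in the configured sets; a code may belong to at
most one class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

DMT_CLASSES = ("IFN", "GA", "fingolimod", "natalizumab")
SYMPTOM_NAMES = (
    "numbness",
    "fatigue",
    "bowel",
    "headache",
    "muscle_weakness",
    "visual",
    "bladder",
    "dizziness",
    "respiration",
    "walking",
)
COMORBIDITY_NAMES = ("depression", "diabetes", "dyslipidemia", "tobacco", "cvd")


def strip_dots(code: str) -> str:
    return str(code).replace(".", "").strip()


def prefix_match(code: str, prefixes) -> bool:
    c = strip_dots(code)
    return any(c.startswith(p) for p in prefixes)


@dataclass
class CharlsonCategory:
    category: str
    prefixes: tuple
    weight: int


@dataclass
class CodeDictionary:
    """Named code sets driving claim classification.

    Parameters mirror the YAML layout: ``ndc`` and ``procedures`` map a drug
    class to a list of codes; ``icd9`` carries the MS set, the exclusionary
    primary-diagnosis set, symptom/comorbidity prefix maps and the Charlson
    category list with integer weights.
    """

    ndc: dict = field(default_factory=dict)
    procedures: dict = field(default_factory=dict)
    ms_prefixes: tuple = ("340",)
    exclusionary_primary: tuple = ()
    symptoms: dict = field(default_factory=dict)
    comorbidities: dict = field(default_factory=dict)
    charlson: list = field(default_factory=list)

    def __post_init__(self):
        self._ndc_lookup = {}
        for cls, codes in self.ndc.items():
            for code in codes:
                code = str(code)
                if self._ndc_lookup.get(code, cls) != cls:
                    raise ValueError(f"NDC {code!r} mapped to more than one drug class")
                self._ndc_lookup[code] = cls
        self._proc_lookup = {}
        for cls, codes in self.procedures.items():
            for code in codes:
                code = str(code)
                if self._proc_lookup.get(code, cls) != cls:
                    raise ValueError(
                        f"procedure {code!r} mapped to more than one drug class"
                    )
                self._proc_lookup[code] = cls
        if not any("340".startswith(p) or p.startswith("340") for p in self.ms_prefixes):
            raise ValueError("MS code set must contain code 340")

    # -- drug classification -------------------------------------------------
    def classify_ndc(self, code) -> str | None:
        return self._ndc_lookup.get(str(code))

    def classify_procedure(self, code) -> str | None:
        return self._proc_lookup.get(str(code))

    def ndc_codes(self, drug_class: str) -> list:
        return list(self.ndc.get(drug_class, []))

    def procedure_codes(self, drug_class: str) -> list:
        return list(self.procedures.get(drug_class, []))

    # -- diagnosis sets ------------------------------------------------------
    def is_ms(self, code) -> bool:
        return prefix_match(code, self.ms_prefixes)

    def is_exclusionary(self, code) -> bool:
        return prefix_match(code, self.exclusionary_primary)

    def charlson_weight(self, code) -> int:
        """Weight of the first Charlson category the code falls in (0 if none)."""
        for cat in self.charlson:
            if prefix_match(code, cat.prefixes):
                return cat.weight
        return 0

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def from_mapping(cls, mapping: dict) -> "CodeDictionary":
        icd9 = mapping.get("icd9", {})
        charlson = [
            CharlsonCategory(
                category=c["category"],
                prefixes=tuple(str(p) for p in c["prefixes"]),
                weight=int(c["weight"]),
            )
            for c in icd9.get("charlson", [])
        ]
        return cls(
            ndc={k: [str(c) for c in v] for k, v in mapping.get("ndc", {}).items()},
            procedures={
                k: [str(c) for c in v] for k, v in mapping.get("procedures", {}).items()
            },
            ms_prefixes=tuple(str(p) for p in icd9.get("ms", ["340"])),
            exclusionary_primary=tuple(
                str(p) for p in icd9.get("exclusionary_primary", [])
            ),
            symptoms={
                k: tuple(str(p) for p in v)
                for k, v in icd9.get("symptoms", {}).items()
            },
            comorbidities={
                k: tuple(str(p) for p in v)
                for k, v in icd9.get("comorbidities", {}).items()
            },
            charlson=charlson,
        )

    def to_mapping(self) -> dict:
        return {
            "ndc": {k: list(v) for k, v in self.ndc.items()},
            "procedures": {k: list(v) for k, v in self.procedures.items()},
            "icd9": {
                "ms": list(self.ms_prefixes),
                "exclusionary_primary": list(self.exclusionary_primary),
                "symptoms": {k: list(v) for k, v in self.symptoms.items()},
                "comorbidities": {k: list(v) for k, v in self.comorbidities.items()},
                "charlson": [
                    {
                        "category": c.category,
                        "prefixes": list(c.prefixes),
                        "weight": c.weight,
                    }
                    for c in self.charlson
                ],
            },
        }

    @classmethod
    def from_yaml(cls, path) -> "CodeDictionary":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)

    @classmethod
    def default(cls) -> "CodeDictionary":
        """The dictionaries shipped with the package (synthetic code values)."""
        ref = resources.files("ms_claims_rwe") / "data" / "dictionaries.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(Path(path))
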