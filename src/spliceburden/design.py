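"""The 2×2×3 experimental design: depletion × drug × replicate."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

DEPLETIONS = ("shCtrl", "shRNF113A")
DRUGS = ("none", "cisplatin")

#: Condition labels: C = control shRNA, no drug; Ccis = control + cisplatin;
#: D = depleted, no drug; Dcis = depleted + cisplatin.
CONDITIONS = ("C", "Ccis", "D", "Dcis")


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    depletion: str
    drug: str
    replicate: int

    def __post_init__(self) -> None:
        if self.depletion not in DEPLETIONS:
            raise ValueError(f"depletion must be one of {DEPLETIONS}")
        if self.drug not in DRUGS:
            raise ValueError(f"drug must be one of {DRUGS}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


def condition_label(sample: SampleDesign) -> str:
    base = "C" if sample.depletion == "shCtrl" else "D"
    return base + ("cis" if sample.drug == "cisplatin" else "")


def default_design(n_replicates: int = 3) -> list[SampleDesign]:
    """Four conditions × ``n_replicates`` biological replicates."""
    design = []
    for depletion in DEPLETIONS:
        for drug in DRUGS:
            for rep in range(1, n_replicates + 1):
                label = condition_label(SampleDesign("x", depletion, drug, rep))
                design.append(
                    SampleDesign(f"{label}_{rep}", depletion, drug, rep)
                )
    return design


def samples_of(design: Sequence[SampleDesign], condition: str) -> list[str]:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return [d.sample_id for d in design if condition_label(d) == condition]


def validate_design(design: Sequence[SampleDesign]) -> None:
    keys = [(d.depletion, d.drug, d.replicate) for d in design]
    if len(set(keys)) != len(keys):
        raise ValueError("(depletion, drug, replicate) must be unique across samples")
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_id must be unique")
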