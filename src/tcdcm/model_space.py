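"""The factorial model space: 9 architectures × 16 modulatory configurations.

Models are enumerated architecture-major (all 16 modulatory configurations
of architecture 1, then architecture 2, ...) so that result tables keep a
stable, documented ordering across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .circuit import Architecture, ModelSpec, ModulationConfig

__all__ = ["enumerate_models", "winning_spec", "FamilyPartition", "family_partition"]

N_ARCHITECTURES = 9
N_MODULATIONS = 16


def enumerate_models() -> list[ModelSpec]:
    """All 144 candidate models, architecture-major, modulation-minor."""
    return [
        ModelSpec(Architecture(a), ModulationConfig(m))
        for a in range(1, N_ARCHITECTURES + 1)
        for m in range(1, N_MODULATIONS + 1)
    ]


def model_index(spec: ModelSpec) -> int:
    """Position of ``spec`` in the canonical enumeration."""
    return (spec.architecture.id - 1) * N_MODULATIONS + (spec.modulation.id - 1)


def winning_spec() -> ModelSpec:
    """The model reported to best explain the low→high beta transition.

    Architecture 9 (thalamocortical afferents to DP and II) with modulatory
    configuration 6 (reciprocal SP–MP, reciprocal REL–RET, plus all four
    extrinsic connections): eight modulated directed edges in total.
    """
    return ModelSpec(Architecture(9), ModulationConfig(6))


@dataclass(frozen=True)
class FamilyPartition:
    """Grouping of the 144 models by one factor of the design."""

    factor: str  # "architecture" | "modulation"
    groups: dict[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        seen: list[int] = []
        for members in self.groups.values():
            seen.extend(members)
        n = N_ARCHITECTURES * N_MODULATIONS
        if sorted(seen) != list(range(n)):
            raise ValueError("family groups must partition all 144 models exactly once")


def family_partition(factor: str) -> FamilyPartition:
    """Partition by ``factor``: 9 families of 16, or 16 families of 9."""
    models = enumerate_models()
    groups: dict[int, list[int]] = {}
    for i, spec in enumerate(models):
        if factor == "architecture":
            key = spec.architecture.id
        elif factor == "modulation":
            key = spec.modulation.id
        else:
            raise ValueError(f"factor must be 'architecture' or 'modulation', got {factor!r}")
        groups.setdefault(key, []).append(i)
    return FamilyPartition(factor=factor, groups={k: tuple(v) for k, v in groups.items()})
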