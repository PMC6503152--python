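"""Shared data containers: spectral data and labelled epoch sets."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

CONDITIONS = ("LB", "HB")


@dataclass
class CrossSpectralData:
    """Per-condition power spectral density of one channel.

    ``spectra`` maps condition labels ("LB"/"HB") to real, non-negative
    densities on the shared ascending frequency grid.  ``source_spectra``
    optionally holds per-population densities, keyed by condition, each an
    array of shape (n_freqs, 6).
    """

    freqs: np.ndarray
    spectra: dict[str, np.ndarray]
    source_spectra: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.size < 2:
            raise ValueError("freqs must be a 1-D grid with at least 2 points")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")
        for cond, g in self.spectra.items():
            g = np.asarray(g, dtype=float)
            if g.shape != self.freqs.shape:
                raise ValueError(f"spectrum for {cond} does not match the grid")
            if not np.all(np.isfinite(g)) or np.any(g < 0):
                raise ValueError(f"spectrum for {cond} must be finite and non-negative")
            self.spectra[cond] = g

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.spectra)

    def covers(self, lo: float, hi: float) -> bool:
        return self.freqs[0] <= lo and self.freqs[-1] >= hi

    def to_dict(self) -> dict:
        out = {
            "freqs": self.freqs.tolist(),
            "spectra": {c: g.tolist() for c, g in self.spectra.items()},
        }
        if self.source_spectra is not None:
            out["source_spectra"] = {
                c: np.asarray(g).tolist() for c, g in self.source_spectra.items()
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CrossSpectralData":
        src = d.get("source_spectra")
        return cls(
            freqs=np.asarray(d["freqs"], dtype=float),
            spectra={c: np.asarray(g, dtype=float) for c, g in d["spectra"].items()},
            source_spectra=None
            if src is None
            else {c: np.asarray(g, dtype=float) for c, g in src.items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "CrossSpectralData":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Epoch:
    """One labelled 500 ms segment of the beta envelope's parent signal."""

    label: str
    samples: np.ndarray
    envelope_area: float
    index: int  # position of the epoch in the original recording

    def __post_init__(self) -> None:
        if self.label not in CONDITIONS:
            raise ValueError(f"epoch label must be LB or HB, got {self.label!r}")
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class EpochSet:
    """Non-overlapping labelled epochs from one recording."""

    fs: float
    epochs: list[Epoch] = field(default_factory=list)
    epoch_ms: float = 500.0

    def __post_init__(self) -> None:
        n = round(self.fs * self.epoch_ms / 1000.0)
        for ep in self.epochs:
            if ep.samples.size != n:
                raise ValueError(
                    f"epoch {ep.index} has {ep.samples.size} samples, expected {n}"
                )
        idx = [ep.index for ep in self.epochs]
        if len(idx) != len(set(idx)):
            raise ValueError("epochs overlap (duplicate indices)")

    def condition(self, label: str) -> list[Epoch]:
        return [ep for ep in self.epochs if ep.label == label]

    def counts(self) -> dict[str, int]:
        return {c: len(self.condition(c)) for c in CONDITIONS}
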