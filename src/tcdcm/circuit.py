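"""Thalamocortical circuit: populations, connectivity, priors and state equations.

The circuit couples a motor-cortex microcircuit of four neural masses —
superficial (SP), middle (MP) and deep (DP) pyramidal cells plus a common
pool of inhibitory interneurons (II) — to a two-mass thalamus made of
excitatory relay cells (REL) and inhibitory reticular cells (RET).

Each mass obeys a critically damped second-order synaptic kernel driven by
the sigmoid-transformed voltages of its afferents,

    v̈_j = ( Σ_k γ_jk S(v_k) + Σ_m λ_jm S(v_m, delayed) + I_j
            − 2 v̇_j − v_j / T_j ) / T_j

so an isolated mass has impulse response h(t) ∝ (t/T) exp(−t/T), peaking at
t = T.  Couplings within a structure (cortex or thalamus) are *intrinsic*
(γ, 1 ms conduction delay); couplings between structures are *extrinsic*
(λ, 8 ms delay).  Glutamatergic edges carry positive sign, GABAergic edges
negative; every self-edge models laminar-specific recurrent inhibition and
is therefore negative regardless of the cell type it sits on.

State vectors are laid out as two blocks, ``[v(6); v̇(6)]``, with
populations ordered (SP, MP, DP, II, REL, RET).

Units: coupling strengths in Hz, time constants and delays in seconds
internally.  The serialized configuration (``CircuitParameters.to_dict``)
uses milliseconds for time constants and delays, mirroring the units the
priors are usually quoted in; ``from_dict`` converts back.  This is the
single place the convention is defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "POPULATIONS",
    "Population",
    "Architecture",
    "ModulationConfig",
    "ModelSpec",
    "CircuitParameters",
    "PRIOR_SD",
    "sigmoid",
    "sigmoid_slope",
    "build_connectivity",
    "dynamics",
    "CORTICAL_EDGES",
    "THALAMIC_EDGES",
    "CORTICOTHALAMIC_EDGES",
]

# --------------------------------------------------------------------------
# populations

POPULATIONS: tuple[str, ...] = ("SP", "MP", "DP", "II", "REL", "RET")
POP_INDEX: dict[str, int] = {p: i for i, p in enumerate(POPULATIONS)}
INHIBITORY = frozenset({"II", "RET"})
CORTICAL_POPS = frozenset({"SP", "MP", "DP", "II"})
THALAMIC_POPS = frozenset({"REL", "RET"})


@dataclass(frozen=True)
class Population:
    """One neural mass of the circuit."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in POPULATIONS:
            raise ValueError(f"unknown population {self.name!r}")

    @property
    def polarity(self) -> str:
        return "inhibitory" if self.name in INHIBITORY else "excitatory"

    @property
    def structure(self) -> str:
        return "cortex" if self.name in CORTICAL_POPS else "thalamus"


def populations() -> tuple[Population, ...]:
    return tuple(Population(p) for p in POPULATIONS)


# --------------------------------------------------------------------------
# edges

Edge = tuple[str, str]  # (source, target)

#: Canonical ordering of the 14 cortical intrinsic edges.  The prior-mean
#: vector in ``CircuitParameters.defaults`` follows this order; the mapping
#: from printed prior means to edges is a package convention and can be
#: overridden by passing an explicit ``gamma_mmc`` vector.
CORTICAL_EDGES: tuple[Edge, ...] = (
    ("SP", "MP"),
    ("MP", "SP"),
    ("SP", "DP"),
    ("DP", "SP"),
    ("SP", "II"),
    ("II", "SP"),
    ("MP", "II"),
    ("II", "MP"),
    ("DP", "II"),
    ("II", "DP"),
    ("SP", "SP"),
    ("MP", "MP"),
    ("II", "II"),
    ("DP", "DP"),
)

#: Thalamic intrinsic edges: relay–reticular loop plus reticular self-inhibition.
THALAMIC_EDGES: tuple[Edge, ...] = (("REL", "RET"), ("RET", "REL"), ("RET", "RET"))

#: Corticothalamic extrinsic edges (always present).
CORTICOTHALAMIC_EDGES: tuple[Edge, ...] = (("DP", "REL"), ("DP", "RET"))


def edge_sign(edge: Edge) -> float:
    """+1 for glutamatergic edges, −1 for GABAergic and all self-edges."""
    src, dst = edge
    if src == dst:
        return -1.0
    return -1.0 if src in INHIBITORY else 1.0


def edge_is_extrinsic(edge: Edge) -> bool:
    src, dst = edge
    return (src in CORTICAL_POPS) != (dst in CORTICAL_POPS)


# --------------------------------------------------------------------------
# model space primitives

#: Laminar targets of thalamocortical afferents for the nine architectures.
ARCHITECTURE_TARGETS: dict[int, tuple[str, ...]] = {
    1: ("SP",),
    2: ("MP",),
    3: ("DP",),
    4: ("SP", "MP"),
    5: ("MP", "DP"),
    6: ("SP", "DP"),
    7: ("SP", "II"),
    8: ("MP", "II"),
    9: ("DP", "II"),
}


@dataclass(frozen=True)
class Architecture:
    """Which cortical populations receive thalamocortical afferents from REL."""

    id: int

    def __post_init__(self) -> None:
        if self.id not in ARCHITECTURE_TARGETS:
            raise ValueError(f"architecture id must be 1–9, got {self.id}")

    @property
    def tc_targets(self) -> tuple[str, ...]:
        return ARCHITECTURE_TARGETS[self.id]

    @property
    def thalamocortical_edges(self) -> tuple[Edge, ...]:
        return tuple(("REL", t) for t in self.tc_targets)


#: Intrinsic modulatory motifs (reciprocal pairs keep a separate condition
#: effect per direction).
_MOTIFS: dict[int, tuple[Edge, ...]] = {
    1: (("SP", "DP"), ("DP", "SP")),
    2: (("SP", "MP"), ("MP", "SP")),
    3: (("II", "II"),),
    4: (("REL", "RET"), ("RET", "REL")),
    5: (("SP", "DP"), ("DP", "SP"), ("REL", "RET"), ("RET", "REL")),
    6: (("SP", "MP"), ("MP", "SP"), ("REL", "RET"), ("RET", "REL")),
    7: (("II", "II"), ("REL", "RET"), ("RET", "REL")),
}


@dataclass(frozen=True)
class ModulationConfig:
    """Which connections carry condition-specific (low→high beta) effects.

    Configurations 1–7 pair one intrinsic motif with all extrinsic
    connections, 8 modulates the extrinsic connections only, 9–15 repeat the
    intrinsic motifs without extrinsic modulation, and 16 is the null
    configuration in which no coupling changes between conditions.
    """

    id: int

    def __post_init__(self) -> None:
        if not 1 <= self.id <= 16:
            raise ValueError(f"modulation id must be 1–16, got {self.id}")

    @property
    def includes_extrinsic(self) -> bool:
        return self.id <= 8

    @property
    def intrinsic_motif(self) -> tuple[Edge, ...]:
        if self.id in (8, 16):
            return ()
        key = self.id if self.id <= 7 else self.id - 8
        return _MOTIFS[key]

    def modulated_edges(self, architecture: Architecture) -> tuple[Edge, ...]:
        """Directed edges carrying a condition effect under ``architecture``.

        Extrinsic modulation only applies to thalamocortical edges that
        exist under the architecture, so the number of condition effects
        ranges from 0 (null) to 8.
        """
        edges = list(self.intrinsic_motif)
        if self.includes_extrinsic:
            edges.extend(CORTICOTHALAMIC_EDGES)
            edges.extend(architecture.thalamocortical_edges)
        return tuple(edges)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: an architecture plus a modulatory configuration."""

    architecture: Architecture
    modulation: ModulationConfig

    @property
    def modulated_edges(self) -> tuple[Edge, ...]:
        return self.modulation.modulated_edges(self.architecture)

    @property
    def label(self) -> str:
        return f"A{self.architecture.id}M{self.modulation.id}"

    def all_edges(self) -> tuple[Edge, ...]:
        return (
            CORTICAL_EDGES
            + THALAMIC_EDGES
            + CORTICOTHALAMIC_EDGES
            + self.architecture.thalamocortical_edges
        )


def make_spec(architecture_id: int, modulation_id: int) -> ModelSpec:
    return ModelSpec(Architecture(architecture_id), ModulationConfig(modulation_id))


# --------------------------------------------------------------------------
# parameters

#: Prior means of the 14 cortical coupling strengths (Hz), in the order of
#: ``CORTICAL_EDGES``.  The magnitude multiset {800×9, 400×4, 200×1} follows
#: the published priors; its assignment to individual edges is a package
#: convention, chosen (once) so that at the prior expectations every
#: population expresses a spectral peak inside the 15–35 Hz band, the
#: circuit is stable under every candidate architecture, and the reported
#: direction of condition effects raises beta power.  Override by passing
#: an explicit ``gamma_mmc`` vector if a different mapping is preferred.
CORTICAL_PRIOR_MEANS: tuple[float, ...] = (
    400.0,  # SP->MP
    800.0,  # MP->SP
    800.0,  # SP->DP
    400.0,  # DP->SP
    800.0,  # SP->II
    800.0,  # II->SP
    800.0,  # MP->II
    400.0,  # II->MP
    800.0,  # DP->II
    800.0,  # II->DP
    800.0,  # SP self
    200.0,  # MP self
    400.0,  # II self
    800.0,  # DP self
)

#: Prior standard deviations of the log-scaling factors.  Each physical
#: parameter is prior-mean × exp(θ) with θ ~ N(0, σ²); delays are fixed
#: (zero prior variance) and are not free parameters.
PRIOR_SD: dict[str, float] = {
    "gamma_mmc": (1 / 16) ** 0.5,
    "gamma_tcr": (1 / 64) ** 0.5,
    "lambda": (1 / 16) ** 0.5,
    "T_mmc": (1 / 16) ** 0.5,
    "T_tcr": (1 / 64) ** 0.5,
    "R_mmc": (1 / 32) ** 0.5,
    "R_tcr": (1 / 16) ** 0.5,
    "B": (1 / 8) ** 0.5,
    "noise": (1 / 128) ** 0.5,
    "L": 64 ** 0.5,
    "J": (1 / 16) ** 0.5,
    "hE": (1 / 32) ** 0.5,
}


@dataclass
class CircuitParameters:
    """All tunable quantities of the circuit, in natural units.

    ``gamma_mmc`` follows :data:`CORTICAL_EDGES`, ``gamma_tcr`` follows
    :data:`THALAMIC_EDGES`, ``lam`` is ordered (DP→REL, DP→RET, REL→target₁,
    REL→target₂).  Time constants are stored in seconds: ``T_mmc`` ordered
    (MP, SP, II, DP), ``T_tcr`` ordered (RET, REL).  ``B`` maps modulated
    directed edges to condition-specific log-scaling effects.  ``J`` holds
    the contributions of (SP, MP, DP) to the observed channel, scaled by the
    observation gain ``L``.  ``hE`` is the prior log-precision of the data.
    """

    gamma_mmc: np.ndarray
    gamma_tcr: np.ndarray
    lam: np.ndarray
    T_mmc: np.ndarray
    T_tcr: np.ndarray
    R_mmc: float = 2.0 / 3.0
    R_tcr: float = 2.0 / 3.0
    B: dict[Edge, float] = field(default_factory=dict)
    d_intrinsic: float = 1e-3
    D_extrinsic: float = 8e-3
    alpha_c: float = 0.0
    beta_c: float = 0.0
    alpha_s: float = 0.0
    beta_s: float = 0.0
    L: float = 1.0
    J: np.ndarray = field(default_factory=lambda: np.array([0.6, 0.2, 0.2]))
    hE: float = 12.0

    def __post_init__(self) -> None:
        self.gamma_mmc = np.asarray(self.gamma_mmc, dtype=float)
        self.gamma_tcr = np.asarray(self.gamma_tcr, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.T_mmc = np.asarray(self.T_mmc, dtype=float)
        self.T_tcr = np.asarray(self.T_tcr, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.gamma_mmc.shape != (14,):
            raise ValueError("gamma_mmc must have 14 entries")
        if self.gamma_tcr.shape != (3,):
            raise ValueError("gamma_tcr must have 3 entries")
        if self.lam.shape != (4,):
            raise ValueError("lam must have 4 entries")
        if self.T_mmc.shape != (4,) or self.T_tcr.shape != (2,):
            raise ValueError("time-constant vectors must have 4 and 2 entries")
        if self.J.shape != (3,):
            raise ValueError("J must have 3 entries (SP, MP, DP)")
        for name in ("gamma_mmc", "gamma_tcr", "lam", "T_mmc", "T_tcr"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} entries must be strictly positive")
        if self.R_mmc <= 0 or self.R_tcr <= 0:
            raise ValueError("sigmoid slopes must be positive")
        if np.any(self.J < 0):
            raise ValueError("J entries must be non-negative")

    # -- construction ------------------------------------------------------

    @classmethod
    def defaults(cls) -> "CircuitParameters":
        """Prior expectations of the baseline (low-beta) condition."""
        return cls(
            gamma_mmc=np.array(CORTICAL_PRIOR_MEANS),
            gamma_tcr=np.array([800.0, 800.0, 800.0]),
            lam=np.array([800.0, 800.0, 800.0, 800.0]),
            T_mmc=np.array([8e-3, 8e-3, 8e-3, 8e-3]),
            T_tcr=np.array([8e-3, 8e-3]),
        )

    # -- derived views -----------------------------------------------------

    @property
    def time_constants(self) -> np.ndarray:
        """Per-population time constants (s) in POPULATIONS order."""
        t_mp, t_sp, t_ii, t_dp = self.T_mmc
        t_ret, t_rel = self.T_tcr
        return np.array([t_sp, t_mp, t_dp, t_ii, t_rel, t_ret])

    @property
    def slopes(self) -> np.ndarray:
        """Per-population sigmoid slopes in POPULATIONS order."""
        return np.array([self.R_mmc] * 4 + [self.R_tcr] * 2)

    def copy(self) -> "CircuitParameters":
        return replace(
            self,
            gamma_mmc=self.gamma_mmc.copy(),
            gamma_tcr=self.gamma_tcr.copy(),
            lam=self.lam.copy(),
            T_mmc=self.T_mmc.copy(),
            T_tcr=self.T_tcr.copy(),
            J=self.J.copy(),
            B=dict(self.B),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """Export with time constants and delays in milliseconds."""
        return {
            "gamma_mmc": self.gamma_mmc.tolist(),
            "gamma_tcr": self.gamma_tcr.tolist(),
            "lambda": self.lam.tolist(),
            "T_mmc_ms": (self.T_mmc * 1e3).tolist(),
            "T_tcr_ms": (self.T_tcr * 1e3).tolist(),
            "R_mmc": self.R_mmc,
            "R_tcr": self.R_tcr,
            "B": {f"{s}->{t}": v for (s, t), v in self.B.items()},
            "d_intrinsic_ms": self.d_intrinsic * 1e3,
            "D_extrinsic_ms": self.D_extrinsic * 1e3,
            "alpha_c": self.alpha_c,
            "beta_c": self.beta_c,
            "alpha_s": self.alpha_s,
            "beta_s": self.beta_s,
            "L": self.L,
            "J": self.J.tolist(),
            "hE": self.hE,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CircuitParameters":
        B = {}
        for key, v in d.get("B", {}).items():
            src, dst = key.split("->")
            B[(src, dst)] = float(v)
        return cls(
            gamma_mmc=np.asarray(d["gamma_mmc"], dtype=float),
            gamma_tcr=np.asarray(d["gamma_tcr"], dtype=float),
            lam=np.asarray(d["lambda"], dtype=float),
            T_mmc=np.asarray(d["T_mmc_ms"], dtype=float) * 1e-3,
            T_tcr=np.asarray(d["T_tcr_ms"], dtype=float) * 1e-3,
            R_mmc=float(d.get("R_mmc", 2 / 3)),
            R_tcr=float(d.get("R_tcr", 2 / 3)),
            B=B,
            d_intrinsic=float(d.get("d_intrinsic_ms", 1.0)) * 1e-3,
            D_extrinsic=float(d.get("D_extrinsic_ms", 8.0)) * 1e-3,
            alpha_c=float(d.get("alpha_c", 0.0)),
            beta_c=float(d.get("beta_c", 0.0)),
            alpha_s=float(d.get("alpha_s", 0.0)),
            beta_s=float(d.get("beta_s", 0.0)),
            L=float(d.get("L", 1.0)),
            J=np.asarray(d.get("J", [0.6, 0.2, 0.2]), dtype=float),
            hE=float(d.get("hE", 12.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CircuitParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# state equations


def sigmoid(v, R: float):
    """Centred logistic firing-rate function, S(v) = 1/(1+e^(−Rv)) − 1/2.

    Bounded in (−1/2, 1/2), odd, strictly increasing, with S(0) = 0 so the
    origin is a fixed point of the unforced circuit.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sigmoid input must be finite")
    if R <= 0:
        raise ValueError("sigmoid slope R must be positive")
    with np.errstate(over="ignore"):  # saturates cleanly at the bounds
        out = 1.0 / (1.0 + np.exp(-R * v)) - 0.5
    return float(out) if out.ndim == 0 else out


def sigmoid_slope(v, R: float):
    """Derivative dS/dv = R σ(Rv)(1−σ(Rv)); equals R/4 at the origin."""
    v = np.asarray(v, dtype=float)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-R * v))
    out = R * s * (1.0 - s)
    return float(out) if out.ndim == 0 else out


def _edge_strengths(spec: ModelSpec, params: CircuitParameters) -> dict[Edge, float]:
    strengths: dict[Edge, float] = {}
    for edge, g in zip(CORTICAL_EDGES, params.gamma_mmc):
        strengths[edge] = g
    for edge, g in zip(THALAMIC_EDGES, params.gamma_tcr):
        strengths[edge] = g
    strengths[("DP", "REL")] = params.lam[0]
    strengths[("DP", "RET")] = params.lam[1]
    for k, edge in enumerate(spec.architecture.thalamocortical_edges):
        strengths[edge] = params.lam[2 + k]
    return strengths


def build_connectivity(
    spec: ModelSpec,
    params: CircuitParameters,
    condition: str = "LB",
):
    """Assemble the signed coupling matrix, delay matrix and input map.

    Returns ``(C, D, inp)`` where ``C[j, k]`` is the signed coupling (Hz)
    from population k onto population j, ``D[j, k]`` the conduction delay
    (s), and ``inp`` the exogenous-input map (1 on MP and REL).  For the
    high-beta condition every modulated edge is scaled by exp(B).
    """
    if condition not in ("LB", "HB"):
        raise ValueError(f"condition must be 'LB' or 'HB', got {condition!r}")
    modulated = set(spec.modulated_edges)
    existing = set(spec.all_edges())
    for edge in params.B:
        if edge not in modulated:
            raise ValueError(
                f"condition effect on {edge[0]}->{edge[1]} is not part of "
                f"modulatory configuration {spec.modulation.id} under "
                f"architecture {spec.architecture.id}"
            )
    if not modulated <= existing:
        missing = modulated - existing
        raise ValueError(f"modulated edges absent from architecture: {sorted(missing)}")

    strengths = _edge_strengths(spec, params)
    C = np.zeros((6, 6))
    D = np.zeros((6, 6))
    for edge, g in strengths.items():
        src, dst = edge
        scale = 1.0
        if condition == "HB" and edge in modulated:
            scale = np.exp(params.B.get(edge, 0.0))
        C[POP_INDEX[dst], POP_INDEX[src]] = edge_sign(edge) * g * scale
        D[POP_INDEX[dst], POP_INDEX[src]] = (
            params.D_extrinsic if edge_is_extrinsic(edge) else params.d_intrinsic
        )
    inp = np.zeros(6)
    inp[POP_INDEX["MP"]] = 1.0
    inp[POP_INDEX["REL"]] = 1.0
    return C, D, inp


def dynamics(
    state: np.ndarray,
    drive: np.ndarray | float,
    spec: ModelSpec,
    params: CircuitParameters,
    v_intrinsic: np.ndarray | None = None,
    v_extrinsic: np.ndarray | None = None,
    condition: str = "LB",
) -> np.ndarray:
    """Time derivative of the 12-component state vector.

    ``drive`` is the exogenous input applied through the input map (scalar
    or per-population vector).  Delayed voltages are resolved by the caller:
    ``v_intrinsic``/``v_extrinsic`` supply the source voltages seen through
    1 ms and 8 ms conduction, both defaulting to the instantaneous voltage.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (12,):
        raise ValueError("state must have 12 components")
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")
    T = params.time_constants
    if np.any(T <= 0):
        raise ValueError("time constants must be positive")
    v, w = state[:6], state[6:]
    v_in = v if v_intrinsic is None else np.asarray(v_intrinsic, dtype=float)
    v_ex = v if v_extrinsic is None else np.asarray(v_extrinsic, dtype=float)

    C, D, inp = build_connectivity(spec, params, condition)
    ext_mask = D >= params.D_extrinsic - 1e-12
    R = params.slopes
    # per-source slope: cortical sources use R_mmc, thalamic use R_tcr
    firing_in = np.array([sigmoid(v_in[k], R[k]) for k in range(6)])
    firing_ex = np.array([sigmoid(v_ex[k], R[k]) for k in range(6)])
    syn = (C * ~ext_mask) @ firing_in + (C * ext_mask) @ firing_ex
    acc = (syn + inp * drive - 2.0 * w - v / T) / T
    return np.concatenate([w, acc])
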