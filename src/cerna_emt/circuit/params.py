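"""Parameters, state layout and perturbation protocols for the EMT circuit.

The circuit couples two double-negative feedback loops in cascade — SNAIL1
against miR-34 and ZEB1 against miR-200 — with explicit miRNA:mRNA complex
species. zeb1 mRNA carries five miR-200 sites (complexes with 1..5 bound
miRNAs), the ceRNA carries one. Degradation of a complex returns a fraction
lambda of its bound miRNA to the free pool (miRNA recycling). An exogenous
decoy 3'UTR species with one site is always part of the state vector; its
production is zero unless a decoy perturbation switches it on.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import yaml

from ..io_formats import ValidationError

#: Order of the state vector.
SPECIES = (
    "snail1_mrna",
    "SNAIL1",
    "miR34",
    "zeb1_mrna",
    "ZEB1",
    "miR200",
    "zeb1_c1",
    "zeb1_c2",
    "zeb1_c3",
    "zeb1_c4",
    "zeb1_c5",
    "cerna_mrna",
    "cerna_c1",
    "decoy",
    "decoy_c1",
)

N_SPECIES = len(SPECIES)
IDX = {name: i for i, name in enumerate(SPECIES)}

REG_MODES = ("act", "rep", "none")

PERTURBATION_KINDS = ("degradation_multiplier", "production_multiplier", "decoy_addition")

#: Species accepting degradation / production perturbations, mapped to the
#: parameter fields they touch.
_DEG_FIELDS = {
    "snail1_mrna": ["g_s"],
    "SNAIL1": ["g_S"],
    "miR34": ["g_34"],
    "zeb1_mrna": ["g_z"],
    "ZEB1": ["g_Z"],
    "miR200": ["g_m"],
    "cerna_mrna": ["g_f"],
    "decoy": ["g_d"],
}
_PROD_FIELDS = {
    "snail1_mrna": ["k0_s", "k_s"],
    "SNAIL1": ["k_S"],
    "miR34": ["k0_34", "k_34"],
    "zeb1_mrna": ["k0_z", "k_z"],
    "ZEB1": ["k_Z"],
    "miR200": ["k0_m", "k_m"],
    "cerna_mrna": ["k_f"],
    "decoy": ["k_d"],
}


@dataclass(frozen=True)
class CircuitParams:
    """Rate constants of the extended cascading-bistable-switch circuit.

    Units: time in hours, abundances in arbitrary concentration units.
    ``lam`` are the recycling ratios of miR-200 released when a zeb1:miR-200
    complex with 1..5 bound miRNAs is degraded; ``lam_f``/``lam_d`` the same
    for the ceRNA and decoy complexes. ``l_trans`` are relative translation
    efficiencies of the partially bound zeb1 mRNA species (free mRNA = 1).
    """

    # snail1 mRNA: signal-activated transcription, SNAIL1 self-repression
    k0_s: float = 0.0003
    k_s: float = 1.8
    K_I: float = 0.6
    n_I: float = 2.0
    K_SS: float = 2.0
    n_SS: float = 2.0
    g_s: float = 0.6
    # SNAIL1 protein: translation repressed by miR-34
    k_S: float = 1.0
    K_34: float = 0.5
    n_34: float = 2.0
    g_S: float = 0.3
    # miR-34: transcription repressed by SNAIL1 and ZEB1
    k0_34: float = 0.001
    k_34: float = 0.15
    K_S34: float = 1.0
    n_S34: float = 2.0
    K_Z34: float = 1.0
    n_Z34: float = 2.0
    g_34: float = 0.05
    # zeb1 mRNA: SNAIL1-activated transcription plus ZEB1 self-activation
    k0_z: float = 0.003
    k_z: float = 1.0
    K_Sz: float = 3.0
    n_Sz: float = 3.0
    k_zZ: float = 0.5
    K_Zz: float = 1.0
    n_Zz: float = 2.0
    g_z: float = 0.6
    # zeb1:miR-200 complexes (5 sites)
    kon: float = 1.0
    koff: float = 0.2
    gc: tuple = (0.2, 0.4, 0.8, 1.6, 3.2)
    lam: tuple = (0.9, 0.9, 0.9, 0.9, 0.9)
    l_trans: tuple = (0.5, 0.2, 0.05, 0.01, 0.0)
    # ZEB1 protein
    k_Z: float = 1.0
    g_Z: float = 0.3
    # miR-200: transcription repressed by ZEB1 and SNAIL1
    k0_m: float = 0.02
    k_m: float = 0.6
    K_Zm: float = 1.0
    n_Zm: float = 3.0
    K_Sm: float = 2.0
    n_Sm: float = 2.0
    g_m: float = 0.02
    # ceRNA (FN1-like): Hill-regulated transcription, one miR-200 site
    k_f: float = 1.0
    mode_Sf: str = "act"
    leak_Sf: float = 0.5
    K_Sf: float = 2.0
    n_Sf: float = 2.0
    mode_Zf: str = "act"
    leak_Zf: float = 0.05
    K_Zf: float = 1.0
    n_Zf: float = 2.0
    kon_f: float = 1.0
    koff_f: float = 0.2
    g_f: float = 0.1
    g_cf: float = 1.0
    lam_f: float = 0.5
    # exogenous decoy 3'UTR (one site); production 0 unless perturbed on
    k_d: float = 0.0
    g_d: float = 0.05
    kon_d: float = 1.0
    koff_d: float = 0.2
    g_cd: float = 1.0
    lam_d: float = 0.5
    # phenotype classification thresholds (set when the YAML is tuned)
    zeb1_lo: float = 0.5
    zeb1_hi: float = 1.5
    mir200_lo: float = 0.2
    mir200_hi: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "gc", tuple(float(v) for v in self.gc))
        object.__setattr__(self, "lam", tuple(float(v) for v in self.lam))
        object.__setattr__(self, "l_trans", tuple(float(v) for v in self.l_trans))
        for name in ("gc", "lam", "l_trans"):
            if len(getattr(self, name)) != 5:
                raise ValidationError(f"{name} must have 5 entries (zeb1 has 5 miR-200 sites)")
        for lam in (*self.lam, self.lam_f, self.lam_d):
            if not 0.0 <= lam <= 1.0:
                raise ValidationError(f"recycling ratio {lam} outside [0, 1]")
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            if isinstance(v, (int, float)) and not f.startswith(("mode_",)) and v < 0:
                raise ValidationError(f"parameter {f} must be >= 0, got {v}")
        for mode in (self.mode_Sf, self.mode_Zf):
            if mode not in REG_MODES:
                raise ValidationError(f"regulation mode {mode!r} not in {REG_MODES}")
        for n in (self.n_I, self.n_SS, self.n_34, self.n_S34, self.n_Z34, self.n_Sz,
                  self.n_Zz, self.n_Zm, self.n_Sm, self.n_Sf, self.n_Zf):
            if n < 1:
                raise ValidationError("Hill coefficients must be >= 1")

    # -- variants ----------------------------------------------------------
    def without_cerna(self) -> "CircuitParams":
        """Base circuit: the ceRNA transcription unit is silenced."""
        return replace(self, k_f=0.0)

    def with_recycling(self, lam: float) -> "CircuitParams":
        """Same circuit with all five zeb1-complex recycling ratios set to ``lam``."""
        return replace(self, lam=(lam,) * 5)

    def to_dict(self) -> dict:
        out = {}
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            out[f] = list(v) if isinstance(v, tuple) else v
        return out


def load_params(path=None) -> CircuitParams:
    """Load circuit parameters from YAML; ``None`` loads the shipped defaults."""
    if path is None:
        return load_preset("default")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return params_from_dict(raw)


def params_from_dict(raw: dict) -> CircuitParams:
    unknown = set(raw) - set(CircuitParams.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown circuit parameter(s): {sorted(unknown)}")
    return CircuitParams(**raw)


def load_preset(name: str) -> CircuitParams:
    """Shipped parameterizations: 'default' (MCF10A-like) or 'a549_like'."""
    ref = importlib.resources.files("cerna_emt").joinpath(f"data/{name}.yaml")
    try:
        raw = yaml.safe_load(ref.read_text()) or {}
    except FileNotFoundError:
        raise ValidationError(f"no shipped parameter preset named {name!r}") from None
    return params_from_dict(raw)


def save_params(params: CircuitParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class Perturbation:
    """A timed perturbation applied to the circuit.

    kinds: ``degradation_multiplier`` and ``production_multiplier`` scale the
    named species' rates (``absolute=True`` overrides the degradation rate to
    ``magnitude`` instead of multiplying); ``decoy_addition`` switches on
    production of the one-site decoy 3'UTR at rate ``magnitude``.
    """

    species: str
    kind: str
    magnitude: float
    t_start: float = 0.0
    t_end: float = np.inf
    absolute: bool = False

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValidationError(f"unknown perturbation kind {self.kind!r}")
        if self.kind != "decoy_addition" and self.species not in _DEG_FIELDS:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.magnitude < 0:
            raise ValidationError("perturbation magnitude must be >= 0")
        if self.t_end <= self.t_start:
            raise ValidationError("perturbation window must have t_end > t_start")

    def active(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


def apply_perturbation(params: CircuitParams, pert: Perturbation) -> CircuitParams:
    """Return a modified copy of ``params`` with one perturbation applied."""
    updates = {}
    if pert.kind == "degradation_multiplier":
        for f in _DEG_FIELDS[pert.species]:
            updates[f] = pert.magnitude if pert.absolute else getattr(params, f) * pert.magnitude
    elif pert.kind == "production_multiplier":
        for f in _PROD_FIELDS[pert.species]:
            updates[f] = getattr(params, f) * pert.magnitude
    else:  # decoy_addition
        updates["k_d"] = pert.magnitude
    return replace(params, **updates)


@dataclass(frozen=True)
class Protocol:
    """Piecewise-constant exogenous TGF-beta signal plus timed perturbations.

    ``segments`` is a sequence of (t_start, t_end, level) covering the
    simulation span without overlap; 4 ng/ml TGF-beta corresponds to the
    saturating dimensionless level 1.0.
    """

    segments: tuple
    perturbations: tuple = ()

    def __post_init__(self):
        segs = tuple((float(a), float(b), float(v)) for a, b, v in self.segments)
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        if not segs:
            raise ValidationError("protocol needs at least one signal segment")
        for (a, b, v) in segs:
            if b <= a:
                raise ValidationError(f"empty signal segment ({a}, {b})")
            if v < 0:
                raise ValidationError("signal level must be >= 0")
        for (_, b0, _), (a1, _, _) in zip(segs, segs[1:]):
            if not np.isclose(b0, a1):
                raise ValidationError("signal segments must be contiguous and non-overlapping")

    @classmethod
    def constant(cls, level: float, t_end: float = np.inf, perturbations=()) -> "Protocol":
        return cls(((0.0, t_end, level),), tuple(perturbations))

    @property
    def span(self) -> tuple:
        return self.segments[0][0], self.segments[-1][1]

    def signal(self, t: float) -> float:
        for (a, b, v) in self.segments:
            if a <= t < b or (t == b == self.segments[-1][1]):
                return v
        raise ValidationError(f"time {t} h outside protocol span {self.span}")

    def breakpoints(self, t0: float, t1: float):
        """Times in (t0, t1) where the signal or active-perturbation set changes."""
        pts = set()
        for (a, b, _) in self.segments:
            pts.update((a, b))
        for p in self.perturbations:
            pts.update((p.t_start, p.t_end))
        return sorted(p for p in pts if t0 < p < t1 and np.isfinite(p))

    def effective_params(self, params: CircuitParams, t: float) -> CircuitParams:
        for p in self.perturbations:
            if p.active(t):
                params = apply_perturbation(params, p)
        return params
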