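"""Linear compartmental models of interorganelle lipid transport.

A pulse of lipid probe delivered to the plasma membrane (PM) redistributes
between organelles by first-order exchange.  The state vector x(t) holds the
fraction of total lipid signal in each compartment and evolves as

    dx/dt = A x,    A[j, i] = k_{i->j},   A[i, i] = -sum_j k_{i->j} - k_dec

where k_{i->j} are transport rate constants (min^-1) and k_dec an optional
uniform first-order content-decay term fixed from mass-spectrometric
quantification of total probe content.  Because the system is linear, the
exact solution x(t) = expm(A t) x0 is used throughout; no numerical
integration error enters the fits.

Preset topologies cover a retrograde family (vesicular PM->Endo->Golgi->ER
chain, a direct non-vesicular PM->ER edge, a summary anterograde ER->PM
rate, and ER<->Mito exchange), variants adding content decay and endosomal
recycling, variants with explicit anterograde vesicular legs, and a reduced
two-compartment PM<->ER exchange model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

logger = logging.getLogger(__name__)

#: canonical compartment order
COMPARTMENTS = ("PM", "Endo", "Golgi", "ER", "Mito")

Edge = tuple[str, str, str]  # (source, destination, rate name)

_RETRO_EDGES: tuple[Edge, ...] = (
    ("PM", "Endo", "k_PM_Endo"),
    ("Endo", "Golgi", "k_Endo_Golgi"),
    ("Golgi", "ER", "k_Golgi_ER"),
    ("PM", "ER", "k_PM_ER"),
    ("ER", "PM", "k_ER_PM"),
    ("ER", "Mito", "k_ER_Mito"),
    ("Mito", "ER", "k_Mito_ER"),
)

_ANTERO_LEGS: tuple[Edge, ...] = (
    ("ER", "Golgi", "k_ER_Golgi"),
    ("Golgi", "Endo", "k_Golgi_Endo"),
    ("Endo", "PM", "k_Endo_PM"),
)

_RECYCLING_EDGE: Edge = ("Endo", "PM", "k_Endo_PM")

PRESET_IDS = ("1a", "2a", "3a", "1b", "2b", "3b", "pm_er")


@dataclass(frozen=True)
class CompartmentModel:
    """Named compartments plus directed first-order exchange edges.

    Parameters
    ----------
    compartments
        Ordered compartment names, a subset of :data:`COMPARTMENTS`.
    edges
        ``(source, destination, rate_name)`` triples; rate names are unique.
    content_decay
        If True the model is simulated with a uniform first-order loss whose
        rate is supplied at solve time (fixed externally, e.g. from the MS
        total-content fit), not fitted.
    preset_id
        Identifier when built from :func:`build_model`.
    """

    compartments: tuple[str, ...]
    edges: tuple[Edge, ...] = ()
    content_decay: bool = False
    preset_id: str | None = None

    def __post_init__(self) -> None:
        names = [e[2] for e in self.edges]
        if len(set(names)) != len(names):
            raise ValueError("rate names must be unique per edge")
        for src, dst, _ in self.edges:
            if src not in self.compartments or dst not in self.compartments:
                raise ValueError(f"edge {src}->{dst} connects undeclared compartments")

    @property
    def rate_names(self) -> tuple[str, ...]:
        return tuple(e[2] for e in self.edges)

    def rate_matrix(self, params: Mapping[str, float], content_decay_rate: float = 0.0) -> np.ndarray:
        """Assemble the generator matrix A for ``dx/dt = A x``."""
        missing = [n for n in self.rate_names if n not in params]
        if missing:
            raise KeyError(f"missing rate constants: {missing}")
        idx = {c: i for i, c in enumerate(self.compartments)}
        n = len(self.compartments)
        a = np.zeros((n, n))
        for src, dst, name in self.edges:
            k = float(params[name])
            if k < 0:
                raise ValueError(f"negative rate constant {name} = {k}")
            a[idx[dst], idx[src]] += k
            a[idx[src], idx[src]] -= k
        if content_decay_rate:
            if content_decay_rate < 0:
                raise ValueError("content decay rate must be >= 0")
            a -= content_decay_rate * np.eye(n)
        return a

    def to_dict(self) -> dict:
        return {
            "compartments": list(self.compartments),
            "edges": [list(e) for e in self.edges],
            "content_decay": self.content_decay,
            "preset_id": self.preset_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompartmentModel":
        return cls(
            compartments=tuple(d["compartments"]),
            edges=tuple(tuple(e) for e in d["edges"]),
            content_decay=bool(d.get("content_decay", False)),
            preset_id=d.get("preset_id"),
        )


@dataclass
class StateTrajectory:
    """Solution of a compartment model on a time grid.

    ``fractions`` has shape ``(n_times, n_compartments)``; ``total_content``
    is the per-time sum, which decays when a content-decay term is active.
    """

    times: np.ndarray
    compartments: tuple[str, ...]
    fractions: np.ndarray
    total_content: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.total_content is None:
            self.total_content = self.fractions.sum(axis=1)

    def __getitem__(self, compartment: str) -> np.ndarray:
        return self.fractions[:, self.compartments.index(compartment)]

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.fractions, index=self.times, columns=list(self.compartments))


def build_model(preset_id: str) -> CompartmentModel:
    """Return one of the frozen preset topologies.

    ``1a``: retrograde vesicular chain PM->Endo->Golgi->ER, direct
    non-vesicular PM->ER, summary anterograde ER->PM, and ER<->Mito.
    ``1b``: 1a plus explicit anterograde vesicular legs ER->Golgi,
    Golgi->Endo, Endo->PM (the summary ER->PM rate is retained as the
    non-vesicular anterograde route).  ``2a``/``2b``: same topologies with a
    content-decay scaling fixed from MS.  ``3a``: 2a plus an endosomal
    recycling edge Endo->PM; ``3b``: 2b (whose anterograde legs already
    include Endo->PM).  ``pm_er``: reduced two-compartment PM<->ER exchange.
    """
    if preset_id not in PRESET_IDS:
        raise ValueError(f"unknown preset {preset_id!r}; valid presets: {', '.join(PRESET_IDS)}")
    if preset_id == "pm_er":
        return CompartmentModel(
            compartments=("PM", "ER"),
            edges=(("PM", "ER", "k_PM_ER"), ("ER", "PM", "k_ER_PM")),
            preset_id="pm_er",
        )
    edges = list(_RETRO_EDGES)
    if preset_id.endswith("b"):
        edges += list(_ANTERO_LEGS)
    if preset_id == "3a":
        edges.append(_RECYCLING_EDGE)
    decay = preset_id[0] in ("2", "3")
    return CompartmentModel(
        compartments=COMPARTMENTS,
        edges=tuple(edges),
        content_decay=decay,
        preset_id=preset_id,
    )


def _check_x0(model: CompartmentModel, x0) -> np.ndarray:
    if isinstance(x0, Mapping):
        vec = np.array([float(x0.get(c, 0.0)) for c in model.compartments])
    else:
        vec = np.asarray(x0, dtype=float)
    if vec.shape != (len(model.compartments),):
        raise ValueError("x0 length does not match compartments")
    if np.any(vec < 0):
        raise ValueError("initial fractions must be non-negative")
    return vec


def simulate(
    model: CompartmentModel,
    params: Mapping[str, float],
    x0,
    times: Sequence[float],
    content_decay_rate: float = 0.0,
) -> StateTrajectory:
    """Solve the linear system exactly via the matrix exponential.

    ``x0`` may be a vector in compartment order or a mapping.  ``times`` are
    minutes, non-negative and sorted.  With a content-decay term the
    trajectory sums shrink as exp(-k_dec t); otherwise mass is conserved to
    machine precision.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted")
    x0v = _check_x0(model, x0)
    a = model.rate_matrix(params, content_decay_rate=content_decay_rate)
    out = np.empty((t.size, x0v.size))
    for i, ti in enumerate(t):
        out[i] = expm(a * ti) @ x0v
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"non-finite solution for preset {model.preset_id} at rates {dict(params)}"
        )
    return StateTrajectory(times=t, compartments=model.compartments, fractions=out)


def analytic_pm_er(k1: float, k2: float, x0_pm: float, t) -> np.ndarray:
    """Closed-form PM fraction for the two-compartment exchange model.

    ``k1`` is the PM->ER rate, ``k2`` the ER->PM rate.  The PM fraction
    relaxes mono-exponentially to the equilibrium value k2/(k1+k2) with rate
    k1+k2:  x_PM(t) = x_eq + (x0_pm - x_eq) exp(-(k1+k2) t).
    """
    t = np.asarray(t, dtype=float)
    if k1 < 0 or k2 < 0:
        raise ValueError("rates must be non-negative")
    if k1 + k2 == 0:
        return np.full_like(t, float(x0_pm))
    x_eq = k2 / (k1 + k2)
    return x_eq + (x0_pm - x_eq) * np.exp(-(k1 + k2) * t)


def quasi_equilibrium(params: Mapping[str, float] | None = None, *, k_pm_er=None, k_er_pm=None):
    """Quasi-equilibrium constant K = k_PM-ER / k_ER-PM.

    K describes a lipid's steady-state partitioning between PM and ER; K > 1
    means net enrichment in the ER.  Accepts either a rate mapping or the
    two rates directly (scalars or Monte Carlo sample arrays).
    """
    if params is not None:
        k_pm_er = params["k_PM_ER"]
        k_er_pm = params["k_ER_PM"]
    k_pm_er = np.asarray(k_pm_er, dtype=float)
    k_er_pm = np.asarray(k_er_pm, dtype=float)
    if np.any(k_er_pm <= 0):
        raise ZeroDivisionError("quasi-equilibrium constant undefined for k_ER_PM <= 0")
    out = k_pm_er / k_er_pm
    return float(out) if out.ndim == 0 else out


def retrograde_nonvesicular_share(params: Mapping[str, float] | None = None, *, k_pm_er=None, k_pm_endo=None):
    """Fraction of retrograde PM exit carried by the direct (non-vesicular) route.

    share = k_PM-ER / (k_PM-ER + k_PM-Endo); the complementary share leaves
    the PM by endocytosis.
    """
    if params is not None:
        k_pm_er = params["k_PM_ER"]
        k_pm_endo = params["k_PM_Endo"]
    k_pm_er = np.asarray(k_pm_er, dtype=float)
    k_pm_endo = np.asarray(k_pm_endo, dtype=float)
    total = k_pm_er + k_pm_endo
    if np.any(total <= 0):
        raise ZeroDivisionError("non-vesicular share undefined when both PM exit rates are zero")
    out = k_pm_er / total
    return float(out) if out.ndim == 0 else out
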