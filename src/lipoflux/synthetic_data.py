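"""Synthetic ground-truth data for every stage of the pipeline.

Emulates the statistical structure of pulse-chase lipid imaging and MS
experiments: 5-6 timepoints spanning 0 min to 24 h, about five fields of
view per timepoint with Gaussian replicate noise on organelle fractions,
transport rate constants one to two orders of magnitude above metabolic
ones, organelle masks with designed overlap regions, and species tables in
which the supplied bifunctional species decays mono-exponentially into
product classes while total probe content is slowly depleted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .cli_io import TimeCourse
from .flux_model import CompartmentModel, simulate
from .metabolism_ms import parse_formula

logger = logging.getLogger(__name__)

#: default timepoint grid (minutes): brackets the early 4/30-min readouts and the 24-h endpoint
DEFAULT_TIMEPOINTS = (0.0, 4.0, 30.0, 120.0, 1440.0)

#: plausible transport rates (min^-1) for a mid-speed PC species: direct
#: non-vesicular PM->ER much faster than endocytic PM->Endo, and a
#: transport/metabolism ratio of 30 at the default k_met = 0.005 min^-1.
DEFAULT_RATES = {
    "k_PM_ER": 0.15,
    "k_ER_PM": 0.075,
    "k_PM_Endo": 0.015,
    "k_Endo_Golgi": 0.05,
    "k_Golgi_ER": 0.05,
    "k_ER_Mito": 0.02,
    "k_Mito_ER": 0.04,
}

#: native lipidome class composition used for MS tables (mol% weights)
NATIVE_COMPOSITION = {"PC": 33.0, "PE": 20.0, "SM": 9.0, "PS": 8.0, "PI": 7.0,
                      "PA": 2.0, "TAG": 15.0, "CE": 4.0, "DAG": 2.0}

#: native sum formulas per class (one representative species);
#: bifunctional analogues replace C2H4 with the diazirine N2.
NATIVE_FORMULAS = {"PC": "C42H82NO8P", "PE": "C39H76NO8P", "SM": "C39H79N2O6P",
                   "PS": "C40H76NO10P", "PI": "C43H81O13P", "PA": "C37H71O8P",
                   "TAG": "C55H98O6", "CE": "C45H78O2", "DAG": "C37H70O5"}

SPECIES_COLUMNS_ORDER = ("species", "lipid_class", "formula", "bifunctional",
                         "supplied", "mol_pct", "time_min", "replicate")


@dataclass(frozen=True)
class GroundTruth:
    """True rate constants and initial state behind a synthetic experiment."""

    rate_params: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    initial_state: dict[str, float] = field(default_factory=lambda: {"PM": 1.0})
    k_met: float = 0.005
    content_decay_rate: float = 0.0003
    seed: int = 0

    def __post_init__(self) -> None:
        for name, k in self.rate_params.items():
            if k < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if self.k_met < 0 or self.content_decay_rate < 0:
            raise ValueError("k_met and content_decay_rate must be >= 0")
        vals = np.array(list(self.initial_state.values()), dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("initial fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("initial fractions must sum to 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate structure: Gaussian per-field noise on fractions, truncated to [0, 1]."""

    sd_fraction: float = 0.02
    n_fields: int = 5
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be >= 0")
        t = np.asarray(self.timepoints, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing and start at 0")


def gen_timecourse(truth: GroundTruth, model: CompartmentModel, noise: NoiseSpec) -> TimeCourse:
    """Simulate the model at the noise grid and add per-field Gaussian noise.

    Each reported mean is the average of ``n_fields`` independent draws
    around the noiseless solution (truncated to [0, 1]); sd is the sample
    s.d. over fields and n the field count.  Raw sums are recorded as-is,
    never renormalized.  Deterministic given ``truth.seed``.
    """
    missing = [n for n in model.rate_names if n not in truth.rate_params]
    if missing:
        raise ValueError(f"ground truth lacks rates required by the model: {missing}")
    decay = truth.content_decay_rate if model.content_decay else 0.0
    x0 = {c: truth.initial_state.get(c, 0.0) for c in model.compartments}
    traj = simulate(model, truth.rate_params, x0, noise.timepoints, content_decay_rate=decay)
    rng = np.random.default_rng(truth.seed)
    rows = []
    for i, t in enumerate(traj.times):
        for j, org in enumerate(model.compartments):
            sol = traj.fractions[i, j]
            fields = np.clip(rng.normal(sol, noise.sd_fraction, size=noise.n_fields), 0.0, 1.0)
            rows.append({
                "time_min": float(t),
                "organelle": org,
                "mean": float(fields.mean()),
                "sd": float(fields.std(ddof=1)) if noise.n_fields > 1 else 0.0,
                "n": noise.n_fields,
            })
    return TimeCourse(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# images


@dataclass
class SyntheticImages:
    """A lipid channel, organelle probability maps, and the per-pixel ground truth."""

    lipid: np.ndarray
    prob_maps: dict[str, np.ndarray]
    true_intensity: dict[str, float]
    true_fractions: dict[str, float]
    owner: np.ndarray  # index into sorted organelle names, -1 outside all masks


def _geometry_mask(geom: Mapping, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    kind = geom.get("shape", "rect")
    if kind == "rect":
        r0, c0, r1, c1 = (int(geom[k]) for k in ("r0", "c0", "r1", "c1"))
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise ValueError(f"rectangle {geom} outside image bounds {shape}")
        mask[r0:r1, c0:c1] = True
    elif kind == "disk":
        rr, cc = draw_disk((geom["r"], geom["c"]), geom["radius"], shape=shape)
        mask[rr, cc] = True
    else:
        raise ValueError(f"unknown geometry shape {kind!r}")
    return mask


def two_rectangles(shape: tuple[int, int] = (64, 64), overlap_frac: float = 0.25,
                   names: tuple[str, str] = ("ER", "PM")) -> dict[str, dict]:
    """Layout helper: two equal-width rectangles sharing ``overlap_frac`` of their area."""
    h, w = shape
    width = int(round(w / (2.0 - overlap_frac)))  # 2*width - overlap = w
    return {
        names[0]: {"shape": "rect", "r0": 0, "c0": 0, "r1": h, "c1": width},
        names[1]: {"shape": "rect", "r0": 0, "c0": w - width, "r1": h, "c1": w},
    }


def gen_images(
    layout: Mapping[str, Mapping],
    per_organelle_intensity: Mapping[str, float],
    overlap_spec: Mapping | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    noise: str = "gaussian",
    noise_sd_frac: float = 0.10,
) -> SyntheticImages:
    """Render a toy lipid channel plus organelle probability maps.

    Every organelle occupies the region its geometry describes; overlap
    regions belong (in ground truth) to exactly one organelle each, chosen
    per pixel by ``overlap_spec`` (default: uniformly at random).  The true
    per-pixel intensity is the owner organelle's mean intensity; the lipid
    channel adds Gaussian noise (s.d. = ``noise_sd_frac`` of the local
    mean; the default emulates moderate camera noise) or Poisson noise.
    Probability maps are 1 inside an organelle's geometry and 0 outside.
    """
    if not layout:
        raise ValueError("empty layout")
    for name, mu in per_organelle_intensity.items():
        if mu < 0:
            raise ValueError(f"intensity for {name!r} must be >= 0")
    rng = np.random.default_rng(seed)
    names = sorted(layout)
    masks = {n: _geometry_mask(layout[n], shape) for n in names}

    owner = np.full(shape, -1, dtype=int)
    stack = np.stack([masks[n] for n in names])
    count = stack.sum(axis=0)
    for i, n in enumerate(names):
        owner[(count == 1) & stack[i]] = i
    amb = count >= 2
    if amb.any():
        members = stack[:, amb]  # (orgs, pix)
        u = rng.random(int(amb.sum()))
        cum = np.cumsum(members / members.sum(axis=0), axis=0)
        owner[amb] = (u[None, :] < cum).argmax(axis=0)

    mu_map = np.zeros(shape)
    for i, n in enumerate(names):
        mu_map[owner == i] = float(per_organelle_intensity[n])
    if noise == "gaussian":
        lipid = mu_map + rng.normal(0.0, noise_sd_frac * np.maximum(mu_map, 0.0))
    elif noise == "poisson":
        lipid = rng.poisson(mu_map).astype(float)
    elif noise == "none":
        lipid = mu_map.copy()
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    lipid = np.clip(lipid, 0.0, None)

    true_intensity = {n: float(lipid[owner == i].sum()) for i, n in enumerate(names)}
    total = sum(true_intensity.values())
    true_fractions = {n: (v / total if total > 0 else 0.0) for n, v in true_intensity.items()}
    prob_maps = {n: masks[n].astype(float) for n in names}
    return SyntheticImages(lipid=lipid, prob_maps=prob_maps,
                           true_intensity=true_intensity, true_fractions=true_fractions,
                           owner=owner)


# ---------------------------------------------------------------------------
# MS species tables


def bifunctional_formula(lipid_class: str) -> str:
    """Formula of the bifunctional analogue: native formula - C2H4 + N2."""
    counts = parse_formula(NATIVE_FORMULAS[lipid_class])
    counts["C"] -= 2
    counts["H"] -= 4
    counts["N"] += 2
    order = [e for e in ("C", "H", "N", "O", "P", "S") if counts.get(e, 0) > 0]
    return "".join(f"{e}{counts[e]}" if counts[e] > 1 else e for e in order)


def gen_ms_table(
    truth: GroundTruth,
    classes: Sequence[str] = ("PC", "PE", "TAG", "CE"),
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    seed: int | None = None,
    supplied_class: str = "PC",
    loading: float = 0.02,
    noise_cv: float = 0.1,
    n_replicates: int = 6,
) -> pd.DataFrame:
    """Generate a species table with mono-exponential probe metabolism.

    At each timepoint t, the supplied species holds exp(-k_met t) of the
    bifunctional pool, the remainder being spread equally over the product
    classes; the bifunctional pool itself is ``loading`` (default 2 mol%,
    within the 1-3% loading regime of cyclodextrin delivery) of the
    lipidome, decaying at ``content_decay_rate``.  Multiplicative Gaussian
    noise with coefficient of variation ``noise_cv`` is applied per
    replicate; raw mol% values are recorded without renormalization.
    Replicate count defaults to 6 (three biological repeats with two
    technical replicates each).
    """
    if truth.k_met < 0 or truth.content_decay_rate < 0:
        raise ValueError("rates must be non-negative")
    if supplied_class not in classes:
        raise ValueError("supplied_class must be among classes")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    product_classes = [c for c in classes if c != supplied_class] or [supplied_class]
    native_classes = sorted(set(NATIVE_COMPOSITION) | set(classes))
    native_weights = np.array([NATIVE_COMPOSITION.get(c, 1.0) for c in native_classes])
    native_weights = native_weights / native_weights.sum()

    rows = []
    for t in timepoints:
        bif_total = 100.0 * loading * math.exp(-truth.content_decay_rate * t)
        supplied_frac = math.exp(-truth.k_met * t)
        for rep in range(1, n_replicates + 1):
            def noisy(x):
                if noise_cv <= 0:
                    return x
                return max(float(x * (1.0 + noise_cv * rng.standard_normal())), 0.0)

            rows.append({
                "species": f"{supplied_class}(Y/18:1)",
                "lipid_class": supplied_class,
                "formula": bifunctional_formula(supplied_class),
                "bifunctional": True, "supplied": True,
                "mol_pct": noisy(bif_total * supplied_frac),
                "time_min": float(t), "replicate": rep,
            })
            per_product = bif_total * (1.0 - supplied_frac) / len(product_classes)
            for cls in product_classes:
                rows.append({
                    "species": f"{cls}(Y/met)",
                    "lipid_class": cls,
                    "formula": bifunctional_formula(cls),
                    "bifunctional": True, "supplied": False,
                    "mol_pct": noisy(per_product),
                    "time_min": float(t), "replicate": rep,
                })
            native_total = 100.0 - bif_total
            for cls, w in zip(native_classes, native_weights):
                rows.append({
                    "species": f"{cls}(native)",
                    "lipid_class": cls,
                    "formula": NATIVE_FORMULAS.get(cls, NATIVE_FORMULAS["PC"]),
                    "bifunctional": False, "supplied": False,
                    "mol_pct": noisy(native_total * w),
                    "time_min": float(t), "replicate": rep,
                })
    return pd.DataFrame(rows, columns=list(SPECIES_COLUMNS_ORDER))
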