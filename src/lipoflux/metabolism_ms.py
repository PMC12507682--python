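"""Probe metabolism from species-resolved shotgun lipidomics tables.

Bifunctional (diazirine + alkyne) lipid probes are distinguished from
native lipids by exact mass: substituting two CH2 groups (28.0313 Da) with
the two diazirine nitrogens (28.0061 Da) leaves the nominal mass unchanged
but shifts the monoisotopic mass by 25.2 mDa, resolvable by ultra-high
resolution FT-MS.  From a species table (mol% per species, timepoint and
replicate) this module computes the fraction of the initially supplied
species within the bifunctional lipidome (a proxy for metabolic
conversion), the total bifunctional share of the lipidome (probe
retention), fits a mono-exponential turnover rate k_met, and relates
metabolism to transport rates.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

#: IUPAC monoisotopic atomic masses (Da), 6 decimals
MONOISOTOPIC_MASS = {
    "H": 1.007825,
    "D": 2.014102,
    "C": 12.0,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
    "Na": 22.989770,
    "K": 38.963707,
    "Cl": 34.968853,
}

SPECIES_COLUMNS = ("species", "lipid_class", "formula", "bifunctional", "supplied",
                   "mol_pct", "time_min", "replicate")

#: nitrogen count of native members per lipid class, for formula-based
#: bifunctional inference (probe = native N count + 2 diazirine nitrogens)
NATIVE_NITROGENS = {"PC": 1, "PE": 1, "PS": 1, "SM": 2, "PA": 0, "PI": 0, "PG": 0,
                    "TAG": 0, "DAG": 0, "CE": 0}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    """Element counts from a Hill-style sum formula like ``C40H78NO8P``."""
    counts: Counter = Counter()
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {elem!r} in {formula!r}")
        counts[elem] += int(num) if num else 1
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str | Counter) -> float:
    """Monoisotopic mass (Da) of a sum formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in counts.items())


def mass_delta(formula_a: str, formula_b: str) -> float:
    """Monoisotopic mass difference m(a) - m(b) in Da, rounded to 4 decimals.

    The signature doublet: mass_delta("N2", "") = 28.0061 and
    mass_delta("C2H4", "") = 28.0313; their 25.2-mDa spacing separates
    diazirine probes from native isobars.
    """
    mb = monoisotopic_mass(formula_b) if formula_b else 0.0
    return round(monoisotopic_mass(formula_a) - mb, 4)


def required_resolving_power(mz: float, delta_m: float) -> float:
    """Minimum FWHM resolving power m/dm to baseline-separate a doublet at m/z."""
    if mz <= 0:
        raise ValueError("m/z must be > 0")
    if delta_m <= 0:
        raise ValueError("delta_m must be > 0")
    return mz / delta_m


def resolution_sufficient(mz: float, delta_m: float, instrument_resolution: float) -> bool:
    """Whether an instrument's resolving power suffices to separate the doublet."""
    return instrument_resolution > required_resolving_power(mz, delta_m)


def infer_bifunctional(formula: str, lipid_class: str) -> bool:
    """Classify a species as bifunctional from its formula: native N count + 2."""
    if lipid_class not in NATIVE_NITROGENS:
        raise ValueError(f"no native nitrogen count known for class {lipid_class!r}")
    n = parse_formula(formula).get("N", 0)
    return n == NATIVE_NITROGENS[lipid_class] + 2


@dataclass
class MetabolismFit:
    """Mono-exponential turnover fit f(t) = f0 * exp(-k_met t).

    When the total decline over the time course is below the refusal
    threshold no rate is fitted (``method = "interpolation"``): the species
    is essentially stable on the observation window and a rate constant
    would be dominated by noise.
    """

    k_met: float
    se: float
    f0: float
    f0_se: float
    method: str = "monoexponential"  # or "interpolation"
    message: str = ""

    @property
    def fitted(self) -> bool:
        return self.method == "monoexponential"

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.f0 * np.exp(-self.k_met * t)

    def to_dict(self) -> dict:
        return {"k_met": self.k_met, "se": self.se, "f0": self.f0,
                "f0_se": self.f0_se, "method": self.method, "message": self.message}


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    if len(table) == 0:
        raise ValueError("empty species table")
    missing = [c for c in ("lipid_class", "bifunctional", "supplied", "mol_pct",
                           "time_min", "replicate") if c not in table.columns]
    if missing:
        raise ValueError(f"species table missing columns: {missing}")
    if (table["mol_pct"] < 0).any():
        raise ValueError("mol% values must be non-negative")
    return table


def _ci_halfwidth(values: np.ndarray, level: float = 0.95) -> float:
    n = len(values)
    if n < 2:
        return math.nan
    return float(stats.t.ppf(0.5 + level / 2, n - 1) * values.std(ddof=1) / math.sqrt(n))


def fraction_supplied(table: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Fraction of the supplied species within the bifunctional lipidome, per timepoint.

    Computed per replicate (supplied mol% / total bifunctional mol%), then
    summarized as mean with a t-distribution confidence interval across
    replicates.  Returns columns ``time_min, mean, ci_low, ci_high, n``;
    fractions in [0, 1].  Timepoints whose bifunctional total is zero in
    every replicate are flagged with NaN (and a warning).
    """
    table = _validate_table(table)
    bif = table[table["bifunctional"].astype(bool)]
    rows = []
    for t, group in bif.groupby("time_min"):
        vals = []
        for _, rep in group.groupby("replicate"):
            total = rep["mol_pct"].sum()
            if total <= 0:
                continue
            vals.append(rep.loc[rep["supplied"].astype(bool), "mol_pct"].sum() / total)
        if not vals:
            logger.warning("timepoint %s has zero bifunctional signal; fraction undefined", t)
            rows.append({"time_min": t, "mean": math.nan, "ci_low": math.nan,
                         "ci_high": math.nan, "n": 0})
            continue
        vals = np.asarray(vals)
        half = _ci_halfwidth(vals, ci_level)
        rows.append({"time_min": t, "mean": float(vals.mean()),
                     "ci_low": float(vals.mean() - half), "ci_high": float(vals.mean() + half),
                     "n": len(vals)})
    return pd.DataFrame(rows).sort_values("time_min").reset_index(drop=True)


def fraction_bifunctional_total(table: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Bifunctional share of the whole lipidome per timepoint (probe retention).

    Per replicate: sum of bifunctional mol% / sum of all mol%; summarized as
    mean with t-distribution CI across replicates.
    """
    table = _validate_table(table)
    rows = []
    for t, group in table.groupby("time_min"):
        vals = []
        for _, rep in group.groupby("replicate"):
            total = rep["mol_pct"].sum()
            if total <= 0:
                continue
            vals.append(rep.loc[rep["bifunctional"].astype(bool), "mol_pct"].sum() / total)
        vals = np.asarray(vals)
        half = _ci_halfwidth(vals, ci_level)
        rows.append({"time_min": t, "mean": float(vals.mean()),
                     "ci_low": float(vals.mean() - half), "ci_high": float(vals.mean() + half),
                     "n": len(vals)})
    return pd.DataFrame(rows).sort_values("time_min").reset_index(drop=True)


def fit_monoexponential(
    times,
    fractions,
    sigma=None,
    min_decline: float = 0.05,
) -> MetabolismFit:
    """Least-squares fit of f(t) = f0 exp(-k_met t) to fraction data.

    Refuses to fit when the relative decline between the first and last
    observation is below ``min_decline`` (the near-stable case, e.g. a
    species with negligible interconversion); the result then carries
    ``method = "interpolation"`` and a NaN rate.  Rising data clip k_met at
    zero with a warning.  Standard errors come from the fit covariance.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size < 3:
        raise ValueError("at least 3 timepoints required")
    if t.size != f.size:
        raise ValueError("times and fractions must have equal length")
    decline = (f[0] - f[-1]) / f[0] if f[0] > 0 else 0.0
    if decline < min_decline:
        if decline < 0:
            logger.warning("fractions increase over time; k_met clipped at 0")
            return MetabolismFit(k_met=0.0, se=math.nan, f0=float(f[0]), f0_se=math.nan,
                                 method="monoexponential", message="increasing data; rate clipped at 0")
        logger.info("decline %.3f below threshold %.3f; linear interpolation instead of fit",
                    decline, min_decline)
        return MetabolismFit(k_met=math.nan, se=math.nan, f0=float(f[0]), f0_se=math.nan,
                             method="interpolation",
                             message=f"total decline {decline:.3f} < {min_decline}; not fitted")
    # initial guess from a log-linear regression on positive values
    pos = f > 0
    slope = np.polyfit(t[pos], np.log(f[pos]), 1)[0] if pos.sum() >= 2 else -1e-3
    p0 = (max(-slope, 1e-6), f[0])

    def model(tt, k, f0):
        return f0 * np.exp(-k * tt)

    popt, pcov = curve_fit(model, t, f, p0=(p0[0], p0[1]), sigma=sigma,
                           absolute_sigma=sigma is not None,
                           bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000)
    perr = np.sqrt(np.diag(pcov))
    return MetabolismFit(k_met=float(popt[0]), se=float(perr[0]),
                         f0=float(popt[1]), f0_se=float(perr[1]))


def fraction_supplied_by_replicate(table: pd.DataFrame) -> pd.DataFrame:
    """Supplied fraction of the bifunctional pool per (timepoint, replicate).

    Returns long-format columns ``time_min, replicate, fraction``; replicates
    with zero bifunctional signal at a timepoint are omitted.
    """
    table = _validate_table(table)
    bif = table[table["bifunctional"].astype(bool)]
    rows = []
    for (t, rep), group in bif.groupby(["time_min", "replicate"]):
        total = group["mol_pct"].sum()
        if total <= 0:
            continue
        rows.append({"time_min": float(t), "replicate": rep,
                     "fraction": group.loc[group["supplied"].astype(bool), "mol_pct"].sum() / total})
    return pd.DataFrame(rows)


def fit_monoexponential_by_replicate(table: pd.DataFrame,
                                     min_decline: float = 0.05) -> MetabolismFit:
    """Turnover rate with replicate-level uncertainty.

    Fits the mono-exponential separately to every replicate's supplied
    fraction time course and reports the mean rate with its standard error
    across replicates (sd / sqrt(n)).  Because replicates are independent
    experiments, this s.e. reflects the full between-replicate variability,
    unlike the covariance s.e. of a single fit to the mean curve.
    """
    per_rep = fraction_supplied_by_replicate(table)
    fits = []
    for _, group in per_rep.groupby("replicate"):
        group = group.sort_values("time_min")
        fit = fit_monoexponential(group["time_min"], group["fraction"], min_decline=min_decline)
        fits.append(fit)
    rates = np.array([f.k_met for f in fits if f.fitted])
    if len(rates) < 2:
        mean_curve = per_rep.groupby("time_min")["fraction"].mean()
        return fit_monoexponential(mean_curve.index, mean_curve.to_numpy(), min_decline=min_decline)
    f0s = np.array([f.f0 for f in fits if f.fitted])
    n = len(rates)
    return MetabolismFit(
        k_met=float(rates.mean()), se=float(rates.std(ddof=1) / math.sqrt(n)),
        f0=float(f0s.mean()), f0_se=float(f0s.std(ddof=1) / math.sqrt(n)),
        message=f"mean of {n} per-replicate fits",
    )


def ratio_with_error(a: float, sa: float, b: float, sb: float) -> tuple[float, float]:
    """a/b with first-order error propagation sqrt((sa/a)^2 + (sb/b)^2) * ratio."""
    if b == 0:
        raise ZeroDivisionError("denominator must be non-zero")
    r = a / b
    if a == 0:
        return 0.0, sa / abs(b)
    return float(r), float(abs(r) * math.sqrt((sa / a) ** 2 + (sb / b) ** 2))


def transport_metabolism_ratio(fit_transport, fit_met: MetabolismFit,
                               rate_name: str = "k_PM_ER") -> tuple[float, float]:
    """k_PM-ER / k_met with propagated s.d.; infinite when k_met = 0.

    ``fit_transport`` is a :class:`~lipoflux.model_fitting.FitResult` (the
    Monte Carlo mean and s.d. of the transport rate are used) or a plain
    ``(mean, sd)`` pair.
    """
    if hasattr(fit_transport, "summary"):
        kt, kt_sd = fit_transport.summary[rate_name]
    else:
        kt, kt_sd = fit_transport
    if not fit_met.fitted or math.isnan(fit_met.k_met):
        raise ValueError("metabolism fit carries no rate (interpolation fallback)")
    if fit_met.k_met == 0:
        logger.warning("k_met = 0; transport/metabolism ratio is infinite")
        return math.inf, math.nan
    return ratio_with_error(kt, kt_sd, fit_met.k_met, fit_met.se)


def correlate_rates(k_met, k_transport):
    """OLS regression and Pearson correlation of metabolism vs transport rates.

    Returns a :class:`scipy.stats._stats_mstats_common.LinregressResult`
    with slope, intercept, rvalue and two-sided pvalue; requires >= 3 species.
    """
    x = np.asarray(k_met, dtype=float)
    y = np.asarray(k_transport, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("at least 3 (k_met, k_transport) pairs required")
    return stats.linregress(x, y)


def read_species_table(path) -> pd.DataFrame:
    """Read a species CSV, coercing flag columns to booleans and validating."""
    frame = pd.read_csv(path)
    missing = [c for c in ("lipid_class", "mol_pct", "time_min", "replicate")
               if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "bifunctional" not in frame.columns:
        if "formula" not in frame.columns:
            raise ValueError(f"{path}: need a 'bifunctional' flag or a 'formula' column")
        frame["bifunctional"] = [
            infer_bifunctional(fm, cl) for fm, cl in zip(frame["formula"], frame["lipid_class"])
        ]
    for col in ("bifunctional", "supplied"):
        if col in frame.columns:
            frame[col] = frame[col].astype(bool)
    return _validate_table(frame)
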