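"""Peak-area quantification: RPAs, calibration curves, retention-of-control.

The quantification signal is the relative peak area RPA = A_s / A_i, the
analyte's peak area divided by its matched isotopically labelled standard's.
Calibration is an ordinary least-squares line RPA vs. concentration fitted on
per-level mean RPAs; retention of a compound under a cyclodextrin treatment
is expressed as a percentage of the untreated control's mean RPA.

Run tables are tidy pandas DataFrames with the columns in
:data:`RUN_TABLE_COLUMNS`; one row is one compound measured in one vial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RUN_TABLE_COLUMNS",
    "CalibrationFit",
    "RetentionResult",
    "AnovaResult",
    "relative_peak_area",
    "fit_calibration",
    "quantify",
    "retention_table",
    "anova_compare",
]

RUN_TABLE_COLUMNS = (
    "vial_id", "treatment", "cd", "dose_g_per_L", "compound", "replicate",
    "area_analyte", "area_standard",
)


def relative_peak_area(a_s, a_i):
    """RPA = A_s / A_i.  Accepts scalars or arrays; requires A_i > 0."""
    a_i_arr = np.asarray(a_i, dtype=float)
    if np.any(a_i_arr <= 0):
        raise ValueError("standard peak area A_i must be > 0")
    return np.asarray(a_s, dtype=float) / a_i_arr if np.ndim(a_s) or np.ndim(a_i) \
        else float(a_s) / float(a_i)


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration line RPA = slope·conc + intercept."""

    compound: str
    slope: float
    intercept: float
    r_squared: float
    level_range: tuple[float, float]
    n_points: int


def fit_calibration(points: Sequence[tuple[float, float]] | pd.DataFrame,
                    compound: str = "", aggregate_replicates: bool = True
                    ) -> CalibrationFit:
    """Fit a straight calibration line to (concentration mg/L, RPA) points.

    When several points share a concentration level and
    ``aggregate_replicates`` is true (the default), replicate RPAs are
    averaged per level before the regression — the conventional presentation
    of a replicated calibration series.  R² is the squared Pearson
    correlation of the fitted points.
    """
    if isinstance(points, pd.DataFrame):
        data = points[["level_mg_per_L", "rpa"]].to_numpy(dtype=float)
    else:
        data = np.asarray(points, dtype=float).reshape(-1, 2)
    if data.shape[0] < 3:
        raise ValueError("calibration needs at least 3 points")
    conc, rpa = data[:, 0], data[:, 1]
    if np.unique(conc).size < 3:
        raise ValueError(
            f"calibration needs >=3 distinct concentration levels, "
            f"got {np.unique(conc).size}")
    if aggregate_replicates:
        frame = pd.DataFrame({"conc": conc, "rpa": rpa}).groupby("conc", sort=True)
        mean = frame.mean().reset_index()
        conc, rpa = mean["conc"].to_numpy(), mean["rpa"].to_numpy()
    fit = stats.linregress(conc, rpa)
    return CalibrationFit(
        compound=compound, slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        level_range=(float(conc.min()), float(conc.max())),
        n_points=int(conc.size),
    )


def quantify(rpa, fit: CalibrationFit):
    """Invert the calibration line: concentration = (RPA − intercept)/slope.

    Negative results are returned as-is with a warning; they are diagnostic
    of blank-level signals, not clipped.
    """
    if fit.slope == 0:
        raise ValueError(f"{fit.compound or 'calibration'}: slope is zero")
    conc = (np.asarray(rpa, dtype=float) - fit.intercept) / fit.slope
    if np.any(conc < 0):
        warnings.warn(
            f"{fit.compound or 'calibration'}: negative concentration(s) "
            "from RPA below the intercept", stacklevel=2)
    return float(conc) if np.ndim(rpa) == 0 else conc


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA over treatment groups plus a compact letter display."""

    f_statistic: float
    p_value: float
    letters: dict[str, str]
    pairwise_p: pd.DataFrame
    alpha: float = 0.05


def anova_compare(groups: Mapping[str, Sequence[float]], alpha: float = 0.05,
                  adjust: str | None = None) -> AnovaResult:
    """One-way ANOVA with pairwise two-sample t-tests at ``alpha``.

    Pairwise comparisons are unadjusted by default (plain t-tests at
    p = 0.05); pass ``adjust='holm'`` for a Holm step-down correction.
    Groups sharing a letter in the compact letter display are not
    significantly different.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = {}
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has {arr.size} replicate(s); need >=2")
        samples[name] = arr

    if all(np.ptp(arr) == 0 for arr in samples.values()) and \
            np.ptp([arr[0] for arr in samples.values()]) == 0:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*samples.values())

    pair_p = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                          columns=names)
    raw = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.ptp(samples[a]) == 0 and np.ptp(samples[b]) == 0:
                p = 1.0 if samples[a][0] == samples[b][0] else 0.0
            else:
                p = float(stats.ttest_ind(samples[a], samples[b]).pvalue)
            raw.append((a, b, p))
    if adjust == "holm":
        order = sorted(range(len(raw)), key=lambda k: raw[k][2])
        m = len(raw)
        running = 0.0
        adjusted = [0.0] * m
        for rank, k in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[k][2]))
            adjusted[k] = running
        raw = [(a, b, adj) for (a, b, _), adj in zip(raw, adjusted)]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}; use None or 'holm'")
    for a, b, p in raw:
        pair_p.loc[a, b] = pair_p.loc[b, a] = p

    letters = _compact_letters(names, samples, pair_p, alpha)
    return AnovaResult(f_statistic=float(f_stat), p_value=float(p_val),
                       letters=letters, pairwise_p=pair_p, alpha=alpha)


def _compact_letters(names, samples, pair_p, alpha) -> dict[str, str]:
    # Greedy insert: groups in descending mean order join every letter class
    # whose members they are all compatible with (p > alpha).
    ordered = sorted(names, key=lambda n: -float(np.mean(samples[n])))
    classes: list[list[str]] = []
    for name in ordered:
        placed = False
        for cls in classes:
            if all(pair_p.loc[name, other] > alpha for other in cls):
                cls.append(name)
                placed = True
        if not placed:
            classes.append([name])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in names}
    for letter, cls in zip(alphabet, classes):
        for name in cls:
            letters[name] += letter
    return letters


@dataclass(frozen=True)
class RetentionResult:
    """Percent-of-control retention per compound × treatment.

    ``table`` columns: ``treatment``, ``compound``, ``mean_rpa``, ``sem_rpa``,
    ``n``, ``percent_of_control``, ``letters`` (empty when replicate counts do
    not allow significance testing).  ``overall`` maps each non-control
    treatment to the arithmetic mean of its per-compound percentages.
    """

    table: pd.DataFrame
    overall: dict[str, float] = field(default_factory=dict)

    def percent(self, compound: str, treatment: str) -> float:
        mask = (self.table["compound"] == compound) & \
               (self.table["treatment"] == treatment)
        if not mask.any():
            raise KeyError(f"no entry for {compound!r} under {treatment!r}")
        return float(self.table.loc[mask, "percent_of_control"].iloc[0])


def retention_table(runs: pd.DataFrame, control_label: str = "control",
                    alpha: float = 0.05) -> RetentionResult:
    """Summarize a run table into retention-of-control percentages.

    Per compound and treatment: RPA replicates are averaged and the treated
    mean is expressed as a percentage of the control mean.  The overall
    percentage of a treatment is the arithmetic mean over its compounds.
    Letter groupings (one-way ANOVA + pairwise t-tests across treatments,
    within compound) are attached when every group has >=2 replicates.
    """
    missing = [c for c in ("treatment", "compound", "area_analyte", "area_standard")
               if c not in runs.columns]
    if missing:
        raise ValueError(f"run table is missing columns: {missing}")
    runs = runs.copy()
    runs["rpa"] = relative_peak_area(runs["area_analyte"], runs["area_standard"])

    treatments = list(dict.fromkeys(runs["treatment"]))
    if control_label not in treatments:
        raise ValueError(
            f"no control group {control_label!r}; treatments present: {treatments}")

    control_means: dict[str, float] = {}
    for compound, sub in runs[runs["treatment"] == control_label].groupby("compound"):
        control_means[compound] = float(sub["rpa"].mean())

    rows = []
    letter_lookup: dict[tuple[str, str], str] = {}
    for compound, sub in runs.groupby("compound", sort=False):
        if compound not in control_means:
            raise ValueError(f"compound {compound!r} has no control measurements")
        groups = {t: g["rpa"].to_numpy() for t, g in sub.groupby("treatment")}
        if len(groups) >= 2 and all(v.size >= 2 for v in groups.values()):
            letter_lookup.update(
                {(compound, t): ltr for t, ltr in
                 anova_compare(groups, alpha=alpha).letters.items()})
        for treatment in treatments:
            if treatment not in groups:
                continue
            vals = groups[treatment]
            mean = float(vals.mean())
            sem = float(stats.sem(vals)) if vals.size > 1 else float("nan")
            rows.append(dict(
                treatment=treatment, compound=compound, mean_rpa=mean,
                sem_rpa=sem, n=int(vals.size),
                percent_of_control=100.0 * mean / control_means[compound],
                letters=letter_lookup.get((compound, treatment), ""),
            ))
    table = pd.DataFrame(rows)
    overall = {
        t: float(table.loc[table["treatment"] == t, "percent_of_control"].mean())
        for t in treatments if t != control_label
    }
    return RetentionResult(table=table, overall=overall)
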