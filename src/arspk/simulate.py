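"""Synthetic trial generator and pregnancy-impact exposure simulation.

The generator emulates the design of the underlying trial: 24 pregnant and
24 non-pregnant women with uncomplicated falciparum malaria, a single
weight-banded oral artesunate dose (1.5 / 2 / 2.5 tablets of 100 mg for
<50 / 50-60 / >60 kg), rich sampling at 0.25-12 h post-dose, log-normal
inter-individual variability, additive log-scale residual error, and
censoring at the assay LLOQs (1.2 ng/mL artesunate, 2.0 ng/mL
dihydroartemisinin). Covariate distributions are truncated normals /
log-normals parameterized to reproduce the published admission
demographics (medians and ranges) per pregnancy group; the distributional
families themselves are a modelling choice, since only medians and ranges
are reported.

Every stochastic operation takes an explicit seed; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import COLUMNS, LLOQ_ARS, LLOQ_DHA, StudyDataset
from .structural import (
    ETA_ORDER,
    PopulationModel,
    individual_parameters,
    secondary_parameters,
    solve_profile,
)

#: nominal post-dose sampling schedule (h)
SAMPLING_TIMES = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0)


def _calibrated_location(target: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal whose *median* equals ``target``.

    Asymmetric truncation shifts the median away from the location, so the
    location solves Phi((lo-m)/s) + Phi((hi-m)/s) = 2 Phi((target-m)/s).
    """
    from scipy.optimize import brentq

    def f(m):
        return (stats.norm.cdf((lo - m) / sd) + stats.norm.cdf((hi - m) / sd)
                - 2.0 * stats.norm.cdf((target - m) / sd))

    # the root lies inside (lo, hi) whenever lo < target < hi; a wider
    # bracket is unusable because f -> 0 at both infinities
    return float(brentq(f, lo, hi, xtol=1e-10))


@dataclass
class _TruncNorm:
    median: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng, n):
        m = _calibrated_location(self.median, self.sd, self.lo, self.hi)
        a = (self.lo - m) / self.sd
        b = (self.hi - m) / self.sd
        return stats.truncnorm.rvs(a, b, loc=m, scale=self.sd,
                                   size=n, random_state=rng)


@dataclass
class _TruncLogNorm:
    median: float
    sdlog: float
    lo: float
    hi: float

    def draw(self, rng, n):
        mu = _calibrated_location(np.log(self.median), self.sdlog,
                                  np.log(self.lo), np.log(self.hi))
        a = (np.log(self.lo) - mu) / self.sdlog
        b = (np.log(self.hi) - mu) / self.sdlog
        return np.exp(stats.truncnorm.rvs(a, b, loc=mu, scale=self.sdlog,
                                          size=n, random_state=rng))


def _default_covariate_dists() -> dict:
    """Per-group covariate distributions matched to the admission table."""
    return {
        1: {  # pregnant
            "WT": _TruncNorm(52.0, 5.0, 46.0, 70.0),
            "PC": _TruncLogNorm(810.0, 1.3, 79.0, 54000.0),
            "HB": _TruncNorm(9.1, 1.0, 7.1, 11.0),
            "AST": _TruncLogNorm(20.0, 0.6, 3.2, 84.0),
            "ALT": _TruncLogNorm(20.3, 0.55, 3.2, 63.0),
            "BIL": _TruncLogNorm(0.45, 0.45, 0.2, 1.9),
        },
        0: {  # non-pregnant
            "WT": _TruncNorm(53.0, 5.0, 45.0, 70.0),
            "PC": _TruncLogNorm(240.0, 1.0, 18.0, 2444.0),
            "HB": _TruncNorm(12.0, 1.3, 7.8, 14.0),
            "AST": _TruncLogNorm(27.9, 0.45, 8.2, 59.8),
            "ALT": _TruncLogNorm(21.75, 0.40, 9.9, 61.2),
            "BIL": _TruncLogNorm(0.5, 0.45, 0.2, 2.0),
        },
    }


@dataclass
class StudyDesign:
    """Trial design constants: group sizes, dosing bands, sampling schedule."""

    n_per_group: int = 24
    sampling_times: tuple = SAMPLING_TIMES
    tablet_strength: float = 100.0  # mg artesunate per tablet
    weight_bands: tuple = ((50.0, 1.5), (60.0, 2.0), (np.inf, 2.5))
    ega_range: tuple = (4.0, 8.0)   # months, pregnant women
    covariate_dists: dict = field(default_factory=_default_covariate_dists)

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_times)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        uppers = [b[0] for b in self.weight_bands]
        if sorted(uppers) != list(uppers) or uppers[-1] != np.inf:
            raise ValueError("weight bands must partition (0, inf)")


def assign_dose(wt: float, design: StudyDesign | None = None) -> float:
    """Weight-band dose (mg artesunate): <50 kg 1.5 tablets, 50-60 kg 2,
    >60 kg 2.5, at 100 mg/tablet."""
    if wt <= 0:
        raise ValueError("weight must be positive")
    design = design or StudyDesign()
    for i, (upper, tablets) in enumerate(design.weight_bands):
        # the lowest band is open above (<50 kg); later bands close at their
        # upper edge (50-60 kg inclusive)
        if (wt < upper) if i == 0 else (wt <= upper):
            return tablets * design.tablet_strength
    raise AssertionError("weight bands do not cover the weight")


def sample_covariates(design: StudyDesign, group: int, n: int,
                      seed) -> pd.DataFrame:
    """Draw n subjects' covariates for one pregnancy group.

    Returns a DataFrame with columns WT, PREG, LNPC, HB, AST, ALT, BIL, EGA.
    """
    if group not in (0, 1):
        raise ValueError("group must be 0 (non-pregnant) or 1 (pregnant)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dists = design.covariate_dists[group]
    out = pd.DataFrame({
        "WT": dists["WT"].draw(rng, n),
        "PREG": group,
        "LNPC": np.log(dists["PC"].draw(rng, n)),
        "HB": dists["HB"].draw(rng, n),
        "AST": dists["AST"].draw(rng, n),
        "ALT": dists["ALT"].draw(rng, n),
        "BIL": dists["BIL"].draw(rng, n),
    })
    if group == 1:
        out["EGA"] = rng.uniform(*design.ega_range, size=n)
    else:
        out["EGA"] = 0.0
    return out


def simulate_study(model: PopulationModel, design: StudyDesign | None = None,
                   seed=None, keep_latent: bool = False) -> StudyDataset:
    """Simulate one synthetic study at the trial design.

    Per subject: covariates drawn per group, etas ~ N(0, omega), a single
    weight-banded dose at t=0, the profile solved at the nominal sampling
    times, additive log-scale residual noise per analyte, and censoring of
    raw concentrations below the analyte LLOQ (BQL=1, DV masked). A
    pre-dose record per analyte is emitted with MDV=1 and never enters the
    likelihood.

    With ``keep_latent=True`` the records carry the uncensored log
    concentration in an extra ``DV_LATENT`` column (dropped on write).
    """
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    cov_parts = []
    for group in (1, 0):
        cov_parts.append(sample_covariates(
            design, group, design.n_per_group,
            rng.integers(0, 2 ** 31 - 1)))
    cov = pd.concat(cov_parts, ignore_index=True)
    cov.index = pd.Index(np.arange(1, len(cov) + 1), name="ID")

    omega_sd = np.array([np.sqrt(model.omega[nm]) for nm in ETA_ORDER])
    sig_sd = {"ars": np.sqrt(model.sigma["ars"]),
              "dha": np.sqrt(model.sigma["dha"])}
    times = np.asarray(design.sampling_times)

    from .datasets import SubjectCovariates

    rows = []
    for sid in cov.index:
        c = cov.loc[sid]
        subj = SubjectCovariates(wt=float(c["WT"]), preg=int(c["PREG"]),
                                 lnpc=float(c["LNPC"]), hb=float(c["HB"]),
                                 ast=float(c["AST"]), alt=float(c["ALT"]),
                                 bil=float(c["BIL"]), ega=float(c["EGA"]))
        dose = assign_dose(subj.wt, design)
        eta = rng.standard_normal(4) * omega_sd
        ind = individual_parameters(model, subj, eta)
        prof = solve_profile(ind, [(0.0, dose)], times)

        base = {"ID": sid, "WT": subj.wt, "PREG": subj.preg,
                "LNPC": subj.lnpc, "HB": subj.hb, "AST": subj.ast,
                "ALT": subj.alt, "BIL": subj.bil, "EGA": subj.ega}
        rows.append({**base, "TIME": 0.0, "DV": np.nan, "EVID": 1, "MDV": 1,
                     "AMT": dose, "CMT": 1, "BQL": 0, "DV_LATENT": np.nan})
        for cmt in (2, 3):  # pre-dose screening samples, excluded from fits
            rows.append({**base, "TIME": 0.0, "DV": np.nan, "EVID": 0,
                         "MDV": 1, "AMT": np.nan, "CMT": cmt, "BQL": 0,
                         "DV_LATENT": np.nan})
        for cmt, conc, analyte, lloq in (
                (2, prof.conc_ars, "ars", model.lloq_ars),
                (3, prof.conc_dha, "dha", model.lloq_dha)):
            noise = rng.standard_normal(len(times)) * sig_sd[analyte]
            logc = np.log(np.maximum(conc, 1e-300)) + noise
            for t, lc in zip(times, logc):
                censored = np.exp(lc) < lloq
                rows.append({**base, "TIME": float(t),
                             "DV": np.nan if censored else float(lc),
                             "EVID": 0, "MDV": 1 if censored else 0,
                             "AMT": np.nan, "CMT": cmt,
                             "BQL": int(censored), "DV_LATENT": float(lc)})
    records = pd.DataFrame(rows)
    records = records.sort_values(["ID", "TIME", "EVID", "CMT"],
                                  ascending=[True, True, False, True],
                                  kind="stable").reset_index(drop=True)
    latent = records["DV_LATENT"].to_numpy()
    records = records.reindex(columns=COLUMNS)
    ds = StudyDataset(records,
                      cov[["WT", "PREG", "LNPC", "HB", "AST", "ALT", "BIL",
                           "EGA"]],
                      model.lloq_ars, model.lloq_dha)
    if keep_latent:
        # uncensored log concentrations for oracle checks, never serialized
        ds.records = ds.records.assign(DV_LATENT=latent)
    return ds


@dataclass
class ExposureComparison:
    """Paired pregnancy exposure comparison (relative AUC / CMAX).

    ``table`` is tidy per simulated subject: group, analyte, metric,
    value, relative value (divided by the non-pregnant group mean).
    ``percentiles`` summarizes the relative values at 10/25/50/75/90%.
    """

    table: pd.DataFrame
    percentiles: pd.DataFrame
    reference_band: tuple = (0.8, 1.2)

    def mean_ratio(self, analyte: str, metric: str) -> float:
        """Mean pregnant / mean non-pregnant exposure ratio."""
        t = self.table[(self.table["analyte"] == analyte)
                       & (self.table["metric"] == metric)]
        m = t.groupby("group")["value"].mean()
        return float(m["pregnant"] / m["non-pregnant"])


def exposure_simulation(model: PopulationModel, n_per_group: int = 1000,
                        seed=None,
                        design: StudyDesign | None = None) -> ExposureComparison:
    """Paired simulation of the pregnancy impact on exposure.

    Each simulated pregnant woman has a non-pregnant twin with identical
    body weight, covariates and random effects, isolating the pregnancy
    covariate effect. AUC uses the closed form F x Dose / CL (exact for
    this linear system); CMAX is read off the analytic profile. Relative
    values are each subject's exposure divided by the non-pregnant group
    mean, as in the published comparison.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    cov = sample_covariates(design, 1, n_per_group,
                            rng.integers(0, 2 ** 31 - 1))
    omega_sd = np.array([np.sqrt(model.omega[nm]) for nm in ETA_ORDER])
    etas = rng.standard_normal((n_per_group, 4)) * omega_sd

    from .datasets import SubjectCovariates
    rows = []
    for i in range(n_per_group):
        c = cov.iloc[i]
        dose = assign_dose(float(c["WT"]), design)
        for group, label in ((1, "pregnant"), (0, "non-pregnant")):
            subj = SubjectCovariates(
                wt=float(c["WT"]), preg=group, lnpc=float(c["LNPC"]),
                hb=float(c["HB"]), ast=float(c["AST"]), alt=float(c["ALT"]),
                bil=float(c["BIL"]), ega=float(c["EGA"]) if group else 0.0)
            ind = individual_parameters(model, subj, etas[i])
            sec = secondary_parameters(ind, dose)
            for analyte in ("ars", "dha"):
                rows.append({"subject": i + 1, "group": label,
                             "analyte": analyte, "metric": "auc",
                             "value": sec[f"auc_{analyte}"]})
                rows.append({"subject": i + 1, "group": label,
                             "analyte": analyte, "metric": "cmax",
                             "value": sec[f"cmax_{analyte}"]})
    table = pd.DataFrame(rows)
    ref_means = (table[table["group"] == "non-pregnant"]
                 .groupby(["analyte", "metric"])["value"].mean())
    table["relative"] = table.apply(
        lambda r: r["value"] / ref_means[(r["analyte"], r["metric"])], axis=1)
    pct = (table.groupby(["group", "analyte", "metric"])["relative"]
           .quantile([0.10, 0.25, 0.50, 0.75, 0.90]).unstack())
    return ExposureComparison(table=table, percentiles=pct)
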