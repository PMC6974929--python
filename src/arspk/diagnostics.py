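"""Model diagnostics: CV%, goodness-of-fit, shrinkage, pcVPC, bootstrap.

Conventions follow standard pharmacometric practice: the coefficient of
variation of a log-normal random effect is ``100 * sqrt(exp(omega^2) - 1)``;
eta shrinkage is ``1 - SD(EBE)/omega``; epsilon shrinkage ``1 - SD(IWRES)``;
the prediction-corrected VPC normalizes observations and simulations by the
ratio of the bin-median population prediction to the individual population
prediction on the arithmetic concentration scale, with separate panels for
the fraction of data below the LLOQ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import StudyDataset
from .estimate import (
    EstimationError,
    FitResult,
    LikelihoodSpec,
    _resample_stratified,
    fit,
)
from .structural import (
    ETA_ORDER,
    PopulationModel,
    individual_parameters,
    solve_profile,
)


def cv_percent(omega2: float) -> float:
    """CV% of a log-normal random effect: ``100 * sqrt(exp(omega2) - 1)``.

    For small variances this approaches ``100 * omega`` (Taylor limit).
    """
    if omega2 < 0:
        raise ValueError("variance must be non-negative")
    return float(100.0 * np.sqrt(np.expm1(omega2)))


# ---------------------------------------------------------------------------
# predictions and residuals
# ---------------------------------------------------------------------------

def _predict_obs(dataset: StudyDataset, model: PopulationModel,
                 etas: dict | None = None) -> pd.DataFrame:
    """Log-scale predictions for every observation record.

    ``etas`` maps subject id -> eta 4-vector (in ETA_ORDER); omitted
    subjects (or etas=None) predict at eta = 0 (population prediction).
    Returns the observation rows with an ``IPRED`` column (log ng/mL).
    """
    obs = dataset.observations().copy()
    obs = obs[obs["TIME"] > 0]
    preds = np.empty(len(obs))
    doses = dataset.records[dataset.records["EVID"] == 1]
    for sid, grp in obs.groupby("ID", sort=False):
        cov = dataset.subject_covariates(sid)
        eta = np.zeros(4) if etas is None else np.asarray(
            etas.get(sid, np.zeros(4)), float)
        ind = individual_parameters(model, cov, eta)
        d = doses[doses["ID"] == sid]
        dose_events = list(zip(d["TIME"], d["AMT"]))
        times = grp["TIME"].to_numpy()
        prof = solve_profile(ind, dose_events, times)
        conc = np.where(grp["CMT"].to_numpy() == 3, prof.conc_dha,
                        prof.conc_ars)
        preds[obs.index.get_indexer(grp.index)] = np.log(
            np.maximum(conc, 1e-300))
    out = obs.reset_index(drop=True)
    out["IPRED"] = preds
    return out


def _full_etas(fitres: FitResult) -> dict:
    """EBE table -> full 4-vector etas keyed by subject."""
    etas = {}
    for sid, row in fitres.ebes.iterrows():
        e = np.zeros(4)
        for j, nm in enumerate(ETA_ORDER):
            if nm in row.index:
                e[j] = row[nm]
        etas[sid] = e
    return etas


def gof_tables(fitres: FitResult, dataset: StudyDataset) -> pd.DataFrame:
    """Observed vs predicted table with conditional weighted residuals.

    One row per quantifiable observation: population prediction PRED
    (eta=0), individual prediction IPRED (at the EBEs), IWRES, and CWRES
    from a first-order linearization of the model about the conditional eta
    modes. Censored records are excluded.
    """
    model = fitres.estimates
    etas = _full_etas(fitres)
    obs_i = _predict_obs(dataset, model, etas)
    obs_p = _predict_obs(dataset, model, None)
    tab = obs_i.rename(columns={"IPRED": "IPRED_LOG"})
    tab["PRED_LOG"] = obs_p["IPRED"]
    tab = tab[tab["BQL"] == 0].reset_index(drop=True)

    sig2 = np.where(tab["CMT"] == 3, model.sigma["dha"], model.sigma["ars"])
    tab["IWRES"] = (tab["DV"] - tab["IPRED_LOG"]) / np.sqrt(sig2)

    # CWRES: linearize f(eta) about the EBE; Cov(y) ~ G Omega G' + Sigma
    cwres = np.empty(len(tab))
    h = 1e-4
    active = [i for i, nm in enumerate(ETA_ORDER) if model.omega[nm] > 0]
    omega = np.diag([model.omega[ETA_ORDER[i]] for i in active])
    for sid, grp in tab.groupby("ID", sort=False):
        eta_hat = etas.get(sid, np.zeros(4))
        y = grp["DV"].to_numpy()
        f_hat = grp["IPRED_LOG"].to_numpy()
        G = np.zeros((len(grp), len(active)))
        for j, dim in enumerate(active):
            ep = eta_hat.copy()
            em = eta_hat.copy()
            ep[dim] += h
            em[dim] -= h
            fp = _predict_subject(dataset, model, sid, grp, ep)
            fm = _predict_subject(dataset, model, sid, grp, em)
            G[:, j] = (fp - fm) / (2 * h)
        mean = f_hat - G @ eta_hat[active]
        cov = G @ omega @ G.T + np.diag(
            np.where(grp["CMT"].to_numpy() == 3, model.sigma["dha"],
                     model.sigma["ars"]))
        L = np.linalg.cholesky(cov)
        cwres[tab.index.get_indexer(grp.index)] = np.linalg.solve(L, y - mean)
    tab["CWRES"] = cwres
    return tab


def _predict_subject(dataset, model, sid, grp, eta):
    cov = dataset.subject_covariates(sid)
    ind = individual_parameters(model, cov, eta)
    doses = dataset.records[(dataset.records["EVID"] == 1)
                            & (dataset.records["ID"] == sid)]
    prof = solve_profile(ind, list(zip(doses["TIME"], doses["AMT"])),
                         grp["TIME"].to_numpy())
    conc = np.where(grp["CMT"].to_numpy() == 3, prof.conc_dha, prof.conc_ars)
    return np.log(np.maximum(conc, 1e-300))


def shrinkage(fitres: FitResult, dataset: StudyDataset | None = None) -> dict:
    """Eta shrinkage per IIV dimension and epsilon shrinkage per analyte (%).

    Eta shrinkage: ``100 * (1 - SD(EBE)/omega)``. Epsilon shrinkage:
    ``100 * (1 - SD(IWRES))`` over quantified observations (requires the
    dataset).
    """
    model = fitres.estimates
    out = {}
    for nm in fitres.ebes.columns:
        w = np.sqrt(model.omega[nm])
        out[f"eta_{nm}"] = float(100.0 * (1.0 - fitres.ebes[nm].std(ddof=1) / w))
    if dataset is not None:
        tab = gof_tables(fitres, dataset)
        for cmt, analyte in ((2, "ars"), (3, "dha")):
            iw = tab.loc[tab["CMT"] == cmt, "IWRES"]
            if len(iw) > 1:
                out[f"eps_{analyte}"] = float(100.0 * (1.0 - iw.std(ddof=1)))
    return out


# ---------------------------------------------------------------------------
# pcVPC
# ---------------------------------------------------------------------------

@dataclass
class VpcResult:
    """Prediction-corrected VPC summary.

    ``stats``: per analyte/bin/percentile, the observed prediction-corrected
    percentile and the simulated 95% band. ``blq``: per analyte/bin, the
    observed BLQ fraction and its simulated 95% band.
    """

    stats: pd.DataFrame
    blq: pd.DataFrame
    n_sim: int

    def coverage(self) -> float:
        """Fraction of (analyte, bin, percentile) cells whose observed value
        lies inside the simulated band."""
        s = self.stats.dropna(subset=["observed"])
        inside = (s["observed"] >= s["sim_lo"]) & (s["observed"] <= s["sim_hi"])
        return float(inside.mean())


def pc_vpc(fitres: FitResult | PopulationModel, dataset: StudyDataset,
           n_sim: int = 2000, bins=None, seed=None,
           percentiles=(5, 50, 95)) -> VpcResult:
    """Prediction-corrected visual predictive check with BLQ panels.

    Observations and simulations are prediction-corrected on the raw
    concentration scale by ``pcY = Y * median(PRED_bin) / PRED_ind`` where
    PRED is the population (eta = 0) prediction; percentile bands come from
    ``n_sim`` simulated replicates of the study design. The BLQ panel uses
    uncorrected values against each analyte's LLOQ. Default binning is one
    bin per nominal sampling time.
    """
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    model = fitres.estimates if isinstance(fitres, FitResult) else fitres
    rng = np.random.default_rng(seed)

    obs = _predict_obs(dataset, model, None)  # PRED at eta=0, log scale
    obs = obs.rename(columns={"IPRED": "PRED_LOG"})
    if bins is None:
        bins = np.sort(obs["TIME"].unique())
    bins = np.asarray(bins, float)
    bin_idx = np.argmin(np.abs(obs["TIME"].to_numpy()[:, None]
                               - bins[None, :]), axis=1)
    obs["BIN"] = bins[bin_idx]
    obs["PRED"] = np.exp(obs["PRED_LOG"])

    med = obs.groupby(["CMT", "BIN"])["PRED"].median()
    obs["PC_FACTOR"] = [med[(c, b)] / p for c, b, p in
                        zip(obs["CMT"], obs["BIN"], obs["PRED"])]

    # observed values: quantified -> raw conc; censored contribute only to BLQ
    obs["CONC"] = np.exp(obs["DV"])
    obs["PCY"] = obs["CONC"] * obs["PC_FACTOR"]

    sig_sd = {2: np.sqrt(model.sigma["ars"]), 3: np.sqrt(model.sigma["dha"])}
    lloq = {2: dataset.lloq_ars, 3: dataset.lloq_dha}
    omega_sd = np.array([np.sqrt(model.omega[nm]) for nm in ETA_ORDER])
    doses = dataset.records[dataset.records["EVID"] == 1]

    # simulate n_sim replicates on the observed design
    sim_pct = {(c, b, q): [] for c in (2, 3) for b in bins for q in percentiles}
    sim_blq = {(c, b): [] for c in (2, 3) for b in bins}
    subj_cache = {}
    for sid, grp in obs.groupby("ID", sort=False):
        d = doses[doses["ID"] == sid]
        subj_cache[sid] = (dataset.subject_covariates(sid),
                           list(zip(d["TIME"], d["AMT"])), grp)
    for _ in range(n_sim):
        sim_rows = {"CMT": [], "BIN": [], "PCY": [], "BLQ": []}
        for sid, (cov, dose_events, grp) in subj_cache.items():
            eta = rng.standard_normal(4) * omega_sd
            ind = individual_parameters(model, cov, eta)
            times = grp["TIME"].to_numpy()
            prof = solve_profile(ind, dose_events, times)
            cmt = grp["CMT"].to_numpy()
            conc = np.where(cmt == 3, prof.conc_dha, prof.conc_ars)
            noise = rng.standard_normal(len(times)) * np.where(
                cmt == 3, sig_sd[3], sig_sd[2])
            sim_conc = np.exp(np.log(np.maximum(conc, 1e-300)) + noise)
            blq_flag = sim_conc < np.where(cmt == 3, lloq[3], lloq[2])
            sim_rows["CMT"].append(cmt)
            sim_rows["BIN"].append(grp["BIN"].to_numpy())
            sim_rows["PCY"].append(sim_conc * grp["PC_FACTOR"].to_numpy())
            sim_rows["BLQ"].append(blq_flag)
        sim = pd.DataFrame({k: np.concatenate(v) for k, v in sim_rows.items()})
        for (c, b), g in sim.groupby(["CMT", "BIN"]):
            nonblq = g.loc[~g["BLQ"], "PCY"]
            for q in percentiles:
                sim_pct[(c, b, q)].append(
                    np.percentile(nonblq, q) if len(nonblq) else np.nan)
            sim_blq[(c, b)].append(float(g["BLQ"].mean()))

    stat_rows = []
    blq_rows = []
    for c, analyte in ((2, "ars"), (3, "dha")):
        for b in bins:
            cell = obs[(obs["CMT"] == c) & (obs["BIN"] == b)]
            if len(cell) == 0:
                warnings.warn(f"empty bin {b} for {analyte}")
                continue
            quant = cell[cell["BQL"] == 0]
            for q in percentiles:
                vals = np.asarray(sim_pct[(c, b, q)], float)
                vals = vals[np.isfinite(vals)]
                stat_rows.append({
                    "analyte": analyte, "bin": b, "percentile": q,
                    "observed": (np.percentile(quant["PCY"], q)
                                 if len(quant) else np.nan),
                    "sim_lo": np.percentile(vals, 2.5) if len(vals) else np.nan,
                    "sim_hi": np.percentile(vals, 97.5) if len(vals) else np.nan,
                    "n_obs": len(quant),
                })
            bvals = np.asarray(sim_blq[(c, b)], float)
            blq_rows.append({
                "analyte": analyte, "bin": b,
                "observed": float(cell["BQL"].mean()),
                "sim_lo": float(np.percentile(bvals, 2.5)),
                "sim_hi": float(np.percentile(bvals, 97.5)),
            })
    return VpcResult(stats=pd.DataFrame(stat_rows),
                     blq=pd.DataFrame(blq_rows), n_sim=n_sim)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Nonparametric bootstrap summary per parameter.

    ``summary`` columns: mean, sd, rse_percent (100*sd/mean), ci_lo, ci_hi
    (nonparametric 2.5/97.5 percentiles).
    """

    summary: pd.DataFrame
    samples: pd.DataFrame
    n_requested: int
    n_successful: int


def bootstrap(dataset: StudyDataset, model: PopulationModel, n: int = 1000,
              seed=None, spec: LikelihoodSpec | None = None,
              fixed: set | frozenset = frozenset(),
              maxiter: int = 200) -> BootstrapResult:
    """Stratified nonparametric bootstrap of the model fit.

    Subjects are resampled with replacement within pregnancy strata,
    preserving stratum sizes; each replicate is refit warm-started from the
    original estimates. Summaries (mean, SD, RSE% = 100*SD/mean, percentile
    CIs) are over successful fits only.
    """
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    spec = spec or LikelihoodSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        boot = _resample_stratified(dataset, rng)
        try:
            f = fit(boot, model, spec, fixed=fixed, maxiter=maxiter)
        except Exception:
            continue
        if not np.isfinite(f.ofv):
            continue
        est = f.estimates
        row = {nm: getattr(est, nm) for nm in
               ("cl_ars", "v_ars", "cl_dha", "v_dha", "mtt",
                "preg_cl_dha", "alt_f", "biomass_f")}
        for k, v in est.omega.items():
            row[f"omega_{k}"] = v
        for k, v in est.sigma.items():
            row[f"sigma_{k}"] = v
        rows.append(row)
    if not rows:
        raise EstimationError("all bootstrap replicates failed")
    samples = pd.DataFrame(rows)
    summ = pd.DataFrame({
        "mean": samples.mean(),
        "sd": samples.std(ddof=1),
        "ci_lo": samples.quantile(0.025),
        "ci_hi": samples.quantile(0.975),
    })
    summ["rse_percent"] = 100.0 * summ["sd"] / summ["mean"].abs()
    return BootstrapResult(summary=summ, samples=samples,
                           n_requested=n, n_successful=len(samples))
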