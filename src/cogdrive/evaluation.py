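"""Subject-level leave-one-out evaluation protocol.

Reproduces the study's validation design on (synthetic) data: train the
encoder and decision model on all-but-one subject, decide for the held-out
subject, and score policies counterfactually over the randomized trials
whose condition matches the decision.  Also provides the embedding
group-separation diagnostic (normalized Gaussian KL between median-split
factor groups) and stepwise factor selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, cohen_kappa_score

from cogdrive.data import extract_snippets, standardize_factors
from cogdrive.decision import (
    DecisionHyper,
    compute_speed_delta_target,
    decide_instantaneous,
    decide_window_averaged,
    fit_decision_model,
)
from cogdrive.nn.train import TrainingConfig, encode_batch, train_encoder

__all__ = [
    "EvalReport",
    "gaussian_kl",
    "kl_separation",
    "decision_agreement_metrics",
    "counterfactual_yellow_speed",
    "stepwise_select",
    "loocv_evaluate",
    "POLICIES",
]

POLICIES = ("no_hmi", "always", "random", "window_averaged", "instantaneous")


# ---------------------------------------------------------------------------
# embedding separation diagnostics
# ---------------------------------------------------------------------------

def gaussian_kl(mu0: np.ndarray, cov0: np.ndarray,
                mu1: np.ndarray, cov1: np.ndarray) -> float:
    """Closed-form KL( N(mu0, cov0) || N(mu1, cov1) )."""
    mu0, mu1 = np.atleast_1d(mu0), np.atleast_1d(mu1)
    cov0, cov1 = np.atleast_2d(cov0), np.atleast_2d(cov1)
    d = mu0.shape[0]
    inv1 = np.linalg.inv(cov1)
    diff = mu1 - mu0
    _, ld0 = np.linalg.slogdet(cov0)
    _, ld1 = np.linalg.slogdet(cov1)
    return 0.5 * (np.trace(inv1 @ cov0) + diff @ inv1 @ diff - d + ld1 - ld0)


def _fit_gaussian(x: np.ndarray, ridge: float = 1e-6):
    mu = x.mean(axis=0)
    xc = x - mu
    cov = xc.T @ xc / len(x)
    if np.linalg.eigvalsh(cov).min() < 1e-10:
        warnings.warn("singular group covariance; applying ridge regularization")
        cov = cov + ridge * np.eye(cov.shape[0])
    return mu, cov


#: KL between two identity-covariance Gaussians at unit separation -- the
#: "ideal clustering" normalizer.
_UNIT_SEPARATION_KL = 0.5


def kl_separation(latents: np.ndarray, values: np.ndarray,
                  split: str = "median") -> float:
    """Normalized symmetric Gaussian KL between the two factor groups.

    Latents are split into low/high groups at the median of ``values``;
    a Gaussian is fitted to each group and the symmetrized (Jeffreys / 2)
    KL is divided by the KL of two unit-separated identity-covariance
    Gaussians.  Invariant to latent-space rotation and group relabeling.
    """
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    values = np.asarray(values, dtype=float)
    if len(values) != len(latents):
        raise ValueError("one value per latent required")
    if split != "median":
        raise NotImplementedError(f"split rule {split!r}")
    lo = values <= np.median(values)
    if lo.sum() < 2 or (~lo).sum() < 2:
        raise ValueError("need at least 2 latents per split group")
    mu_a, cov_a = _fit_gaussian(latents[lo])
    mu_b, cov_b = _fit_gaussian(latents[~lo])
    sym = 0.5 * (gaussian_kl(mu_a, cov_a, mu_b, cov_b)
                 + gaussian_kl(mu_b, cov_b, mu_a, cov_a))
    return float(sym / _UNIT_SEPARATION_KL)


# ---------------------------------------------------------------------------
# decision scoring
# ---------------------------------------------------------------------------

def decision_agreement_metrics(decisions: Sequence[bool],
                               labels: Sequence[bool]) -> tuple[float, float]:
    """(Cohen's kappa, balanced accuracy) of decisions against benefit labels."""
    decisions = np.asarray(decisions, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if decisions.shape != labels.shape:
        raise ValueError("decisions and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("balanced accuracy undefined for single-class labels")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-decision policies
        kappa = float(cohen_kappa_score(labels, decisions))
        bacc = float(balanced_accuracy_score(labels, decisions))
    if np.isnan(kappa):
        kappa = 0.0
    return kappa, bacc


def counterfactual_yellow_speed(
    decisions: dict[str, bool],
    trials: pd.DataFrame,
) -> tuple[float, float, int]:
    """Score a per-subject policy on the trials matching its decision.

    For each subject, yellow-trial mean speeds are averaged over the trials
    whose experimental condition (interface present / absent) matches the
    policy's decision.  Returns the across-subject mean, its standard error,
    and the number of subjects excluded for lack of matching trials.
    """
    values = []
    excluded = 0
    for sid, deploy in decisions.items():
        sub = trials[(trials["subject_id"] == sid) & trials["had_yellow"]]
        match = sub[sub["condition"] != "none"] if deploy else sub[sub["condition"] == "none"]
        if match.empty:
            warnings.warn(f"subject {sid}: no trials matching the decision; excluded")
            excluded += 1
            continue
        values.append(float(match["mean_yellow_speed"].mean()))
    if not values:
        raise ValueError("no subject had trials matching its decision")
    values = np.asarray(values)
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return float(values.mean()), se, excluded


# ---------------------------------------------------------------------------
# stepwise factor selection
# ---------------------------------------------------------------------------

def _fit_criterion(X: pd.DataFrame, y: np.ndarray, cols: list[str],
                   criterion: str) -> float:
    """Model-fit score where larger is better."""
    import statsmodels.api as sm

    n = len(y)
    if not cols:
        if criterion == "adj_r2":
            return 0.0
        resid = y - y.mean()
        sigma2 = (resid**2).mean()
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        return -(2 * 1 - 2 * llf)  # -AIC of the intercept-only model
    model = sm.OLS(y, sm.add_constant(X[cols].to_numpy(float))).fit()
    if criterion == "adj_r2":
        return float(model.rsquared_adj)
    if criterion == "aic":
        return float(-model.aic)
    raise ValueError(f"unknown criterion {criterion!r}")


def _stepwise_pvalue(candidates: pd.DataFrame, y: np.ndarray,
                     alpha_in: float, alpha_out: float,
                     max_iter: int) -> list[str]:
    import statsmodels.api as sm

    selected: list[str] = []
    remaining = list(candidates.columns)
    for _ in range(max_iter):
        changed = False
        # forward: enter the candidate with the smallest significant p-value
        best_p, best_col = alpha_in, None
        for col in remaining:
            m = sm.OLS(y, sm.add_constant(
                candidates[selected + [col]].to_numpy(float))).fit()
            p = float(m.pvalues[-1])
            if p < best_p:
                best_p, best_col = p, col
        if best_col is not None:
            selected.append(best_col)
            remaining.remove(best_col)
            changed = True
        # backward: drop the least significant predictor
        while selected:
            m = sm.OLS(y, sm.add_constant(
                candidates[selected].to_numpy(float))).fit()
            pvals = m.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] <= alpha_out:
                break
            remaining.append(selected.pop(worst))
            changed = True
        if not changed:
            break
    return selected


def stepwise_select(
    candidates: pd.DataFrame,
    behavior: Sequence[float],
    criterion: str = "pvalue",
    alpha: float = 0.01,
    max_iter: int = 100,
) -> list[str]:
    """Forward-selection / backward-elimination on a linear model.

    Adds the predictor producing the largest fit improvement, then removes
    predictors whose loss is smallest, until no further improvement.  The
    default criterion enters/removes on OLS t-test p-values at ``alpha``
    (a pure adjusted-R-squared rule admits any |t| > 1 and selects noise
    variables on null data); ``adj_r2`` and ``aic`` are also available.
    """
    y = np.asarray(behavior, dtype=float)
    if candidates.empty or len(y) != len(candidates):
        raise ValueError("candidates and behavior must align and be non-empty")
    if criterion == "pvalue":
        return _stepwise_pvalue(candidates, y, alpha, alpha, max_iter)
    selected: list[str] = []
    remaining = list(candidates.columns)
    current = _fit_criterion(candidates, y, selected, criterion)
    for _ in range(max_iter):
        changed = False
        # forward: best single addition
        best_gain, best_col = 0.0, None
        for col in remaining:
            score = _fit_criterion(candidates, y, selected + [col], criterion)
            if score - current > best_gain + 1e-12:
                best_gain, best_col = score - current, col
        if best_col is not None:
            selected.append(best_col)
            remaining.remove(best_col)
            current += best_gain
            changed = True
        # backward: drop whichever removal most improves the criterion
        while selected:
            best_drop, best_score = None, current
            for col in selected:
                rest = [c for c in selected if c != col]
                score = _fit_criterion(candidates, y, rest, criterion)
                if score > best_score + 1e-12:
                    best_drop, best_score = col, score
            if best_drop is None:
                break
            selected.remove(best_drop)
            remaining.append(best_drop)
            current = best_score
            changed = True
        if not changed:
            break
    return selected


# ---------------------------------------------------------------------------
# LOOCV pipeline
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Aggregated LOOCV results across seeds."""

    policies: dict[str, dict[str, float]]      # policy -> mean_speed, se, kappa, bacc
    kl_separation: dict[str, float]            # factor -> normalized KL
    per_seed: list[dict] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    n_subjects: int = 0
    excluded_subjects: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        import json

        return json.dumps({
            "policies": self.policies,
            "kl_separation": self.kl_separation,
            "seeds": self.seeds,
            "n_subjects": self.n_subjects,
            "excluded_subjects": self.excluded_subjects,
            "per_seed": self.per_seed,
        }, indent=2)

    def policy_table(self) -> pd.DataFrame:
        rows = [{"policy": k, **v} for k, v in self.policies.items()]
        return pd.DataFrame(rows)


def _training_set_ids(snippets, held_out: str) -> frozenset:
    return frozenset((s.subject_id, s.lap_id, s.approach_idx)
                     for s in snippets if s.subject_id != held_out)


def loocv_evaluate(
    bundle,
    train_config: TrainingConfig,
    decision_hyper: DecisionHyper = DecisionHyper(),
    seeds: Sequence[int] | int = 10,
    window: int = 50,
    factor_names: Sequence[str] | None = None,
    audit: list | None = None,
) -> EvalReport:
    """Leave-one-subject-out evaluation, averaged over seeds.

    Per fold: the encoder and the SVR are trained on the remaining subjects
    (factor standardization fitted on the training subjects only), the
    held-out subject's snippets are encoded, and deployment is decided.
    Policies are scored counterfactually on the held-out subjects' own
    randomized trials.  ``audit``, if given, collects per-fold training-set
    identifier hashes for leakage checking.
    """
    if isinstance(seeds, int):
        seeds = list(range(seeds))
    seeds = list(seeds)
    trials = bundle.analysis_trials
    subjects_df = bundle.subjects
    factor_names = list(factor_names or bundle.factor_names)

    snippets, _ = extract_snippets(
        bundle.logs[~bundle.logs["is_practice"]], window=window)
    by_subject: dict[str, list] = {}
    for s in snippets:
        by_subject.setdefault(s.subject_id, []).append(s)

    # per-subject measured targets; drop subjects lacking either condition
    targets: dict[str, float] = {}
    excluded: list[str] = []
    for sid in subjects_df["subject_id"]:
        sub_trials = trials[trials["subject_id"] == sid]
        try:
            t = compute_speed_delta_target(sub_trials)
        except ValueError as e:
            warnings.warn(f"excluding subject: {e}")
            excluded.append(sid)
            continue
        if sid not in by_subject:
            warnings.warn(f"excluding subject {sid}: no usable snippets")
            excluded.append(sid)
            continue
        targets[sid] = t
    eligible = sorted(targets)
    if len(eligible) < 3:
        raise ValueError("LOOCV requires at least 3 eligible subjects")
    labels = {sid: targets[sid] < 0 for sid in eligible}

    per_seed_reports: list[dict] = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        decisions = {p: {} for p in POLICIES}
        heldout_latents: dict[str, np.ndarray] = {}
        for fold, held in enumerate(eligible):
            train_ids = [sid for sid in eligible if sid != held]
            train_snips = [s for sid in train_ids for s in by_subject[sid]]
            if audit is not None:
                audit.append({"seed": seed, "held_out": held,
                              "train_set": _training_set_ids(train_snips, held)})
            train_table = subjects_df[subjects_df["subject_id"].isin(train_ids)]
            profiles, _tf = standardize_factors(train_table, factor_names)
            cfg = replace(train_config, seed=seed * 10007 + fold)
            model = train_encoder(train_snips, profiles, cfg,
                                  factor_names=factor_names)
            all_z = encode_batch(
                [s for sid in eligible for s in by_subject[sid]], model.encoder)
            latents, pos = {}, 0
            for sid in eligible:
                n_i = len(by_subject[sid])
                latents[sid] = all_z[pos: pos + n_i]
                pos += n_i
            z_held = latents.pop(held)
            dmodel = fit_decision_model(latents, targets, decision_hyper)
            heldout_latents[held] = z_held
            decisions["window_averaged"][held] = decide_window_averaged(dmodel, z_held)
            decisions["instantaneous"][held] = decide_instantaneous(dmodel, z_held[-1])
            decisions["no_hmi"][held] = False
            decisions["always"][held] = True
            decisions["random"][held] = bool(rng.integers(2))

        seed_report = {"seed": seed, "policies": {}}
        for policy in POLICIES:
            dec = decisions[policy]
            mean, se, n_excl = counterfactual_yellow_speed(dec, trials)
            kappa, bacc = decision_agreement_metrics(
                [dec[s] for s in eligible], [labels[s] for s in eligible])
            seed_report["policies"][policy] = {
                "mean_speed": mean, "se": se, "kappa": kappa,
                "balanced_accuracy": bacc, "n_excluded": n_excl,
            }

        factor_lookup = subjects_df.set_index("subject_id")[factor_names].to_dict("index")
        pooled = np.concatenate([heldout_latents[s] for s in eligible])
        pooled_vals = {
            f: np.concatenate([
                np.full(len(heldout_latents[s]), float(factor_lookup[s][f]))
                for s in eligible
            ]) for f in factor_names
        }
        seed_report["kl_separation"] = {
            f: kl_separation(pooled, pooled_vals[f]) for f in factor_names}
        per_seed_reports.append(seed_report)

    agg_policies = {}
    for policy in POLICIES:
        agg_policies[policy] = {
            key: float(np.mean([r["policies"][policy][key] for r in per_seed_reports]))
            for key in ("mean_speed", "se", "kappa", "balanced_accuracy")
        }
    agg_kl = {
        f: float(np.mean([r["kl_separation"][f] for r in per_seed_reports]))
        for f in factor_names
    }
    return EvalReport(policies=agg_policies, kl_separation=agg_kl,
                      per_seed=per_seed_reports, seeds=seeds,
                      n_subjects=len(eligible), excluded_subjects=excluded)
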