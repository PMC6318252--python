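"""Accuracy metrics and synthetic-data generation.

Compares predicted against measured logPFs (signed and absolute
differences, Pearson correlation) and propagates both PF sets into
deuterium-uptake profiles so prediction error can be quantified on the
deuteration (Da) scale — small logPF errors can be large on the PF scale
(a logPF difference of 2 is a 100-fold PF ratio) and correspondingly large
in expected deuterons.

The synthetic generator draws covariates from a configurable distribution
and measured logPFs from the log-linear model's own assumed structure
(linear predictor plus Gaussian residual), which makes parameter-recovery
and end-to-end pipeline tests possible without experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .deuteration import peptide_uptake, profile_difference
from .features import ResidueFeatures
from .predictors import CoefficientSet, design_row
from .structure_io import PeptideDef

__all__ = [
    "AccuracyReport",
    "CovariateSpec",
    "InsufficientOverlapError",
    "compare_logpf",
    "deuteration_error",
    "simulate_pf_dataset",
    "train_test_split",
]


class InsufficientOverlapError(ValueError):
    """Fewer than two residues are shared between the two PF tables."""


@dataclass
class AccuracyReport:
    """Agreement between predicted and measured logPFs over one subset."""

    n: int
    signed_mean: float           # mean of (predicted - measured)
    mean_abs: float
    max_abs: float
    pearson_r: float
    subset: str = "all"
    signed: pd.Series | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {"n": self.n, "signed_mean": self.signed_mean,
                "mean_abs": self.mean_abs, "max_abs": self.max_abs,
                "pearson_r": self.pearson_r, "subset": self.subset}


def compare_logpf(measured: pd.DataFrame, predicted: pd.DataFrame,
                  subset: str = "all", scale: str = "logpf"
                  ) -> AccuracyReport:
    """Accuracy report over the residues shared by two PF tables.

    Both tables need ``chain``/``residue``/``logpf`` columns.  When
    ``subset`` is ``"train"`` or ``"test"`` and the measured table carries a
    ``set_label`` column, the comparison is restricted accordingly.
    Differences are reported predicted − measured; the correlation is
    computed on the logPF scale unless ``scale="pf"``.
    """
    m = measured.set_index(["chain", "residue"])["logpf"]
    if subset in ("train", "test") and "set_label" in measured.columns:
        lab = measured.set_index(["chain", "residue"])["set_label"]
        m = m[lab == subset]
    p = predicted.set_index(["chain", "residue"])["logpf"]
    common = m.index.intersection(p.index)
    if len(common) < 2:
        raise InsufficientOverlapError(
            f"only {len(common)} shared residue(s); need at least 2")
    mv, pv = m.loc[common].astype(float), p.loc[common].astype(float)
    if scale == "pf":
        mv, pv = 10.0 ** mv, 10.0 ** pv
    elif scale != "logpf":
        raise ValueError("scale must be 'logpf' or 'pf'")
    signed = pv - mv
    if np.ptp(mv.values) == 0 or np.ptp(pv.values) == 0:
        r = 1.0 if np.allclose(signed, signed.iloc[0]) else np.nan
    else:
        r = float(stats.pearsonr(mv.values, pv.values).statistic)
    return AccuracyReport(
        n=len(common),
        signed_mean=float(signed.mean()),
        mean_abs=float(signed.abs().mean()),
        max_abs=float(signed.abs().max()),
        pearson_r=r,
        subset=subset,
        signed=signed,
    )


def deuteration_error(measured: pd.DataFrame, predicted: pd.DataFrame,
                      peptides: list[PeptideDef],
                      times, k_int: dict[int, float],
                      back_exchange: float = 1.0) -> pd.DataFrame:
    """Per-peptide uptake differences between two PF sources.

    Simulates each peptide's uptake from the measured and from the
    predicted PF table and returns a tidy long-format frame with columns
    ``peptide_id, time_s, d_measured, d_predicted, difference`` where
    ``difference = d_measured - d_predicted``.
    """
    m = {int(r.residue): float(r.logpf) for r in measured.itertuples()}
    p = {int(r.residue): float(r.logpf) for r in predicted.itertuples()}
    rows = []
    for pep in peptides:
        prof_m = peptide_uptake(pep, m, k_int, times, back_exchange,
                                source="measured")
        prof_p = peptide_uptake(pep, p, k_int, times, back_exchange,
                                source="predicted")
        diff, _, _ = profile_difference(prof_m, prof_p)
        for t, dm, dp, dd in zip(prof_m.times, prof_m.d, prof_p.d, diff):
            rows.append((pep.peptide_id, float(t), float(dm), float(dp),
                         float(dd)))
    return pd.DataFrame(
        rows, columns=["peptide_id", "time_s", "d_measured", "d_predicted",
                       "difference"])


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------

@dataclass
class CovariateSpec:
    """Sampling distribution of the model covariates.

    Category probabilities follow the composition of a typical folded
    protein HX dataset (most amides hydrogen-bond to main-chain oxygens;
    burial centred near the observed training-set average of ~59 heavy
    atoms).
    """

    motion_probs: dict[str, float] = field(default_factory=lambda: {
        "L": 0.3, "UD": 0.25, "EX1": 0.2, "UD+EX1": 0.25})
    ss_probs: dict[str, float] = field(default_factory=lambda: {
        "no": 0.3, "helix": 0.4, "beta-sheet": 0.3})
    hbond_probs: dict[str, float] = field(default_factory=lambda: {
        "no": 0.05, "Hbond-with-H2O": 0.03,
        "Hbond-with-mainchain-O": 0.85, "Hbond-with-sidechain-O": 0.07})
    burial_mean: float = 59.1
    burial_sd: float = 15.0

    def validate(self):
        for name, probs in (("motion", self.motion_probs),
                            ("ss", self.ss_probs),
                            ("hbond", self.hbond_probs)):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
            if max(probs.values()) == 1.0:
                import warnings
                warnings.warn(f"degenerate {name} distribution: a single "
                              "category has probability 1 (the fit design "
                              "will be rank-deficient)")


def simulate_pf_dataset(coeffs: CoefficientSet, n: int,
                        spec: CovariateSpec | None = None,
                        sigma: float = 0.3, seed: int = 0,
                        chain: str = "A"
                        ) -> tuple[pd.DataFrame, list[ResidueFeatures]]:
    """Draw a synthetic per-residue PF dataset from the log-linear model.

    Covariates are sampled from ``spec``; measured logPFs are the linear
    predictor of ``coeffs`` plus N(0, sigma^2) noise.  Returns an
    annotation-table DataFrame and the matching feature list; deterministic
    for a fixed ``seed``.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    spec = spec or CovariateSpec()
    spec.validate()
    rng = np.random.default_rng(seed)

    def _draw(probs: dict[str, float]) -> np.ndarray:
        cats = list(probs)
        return rng.choice(cats, size=n, p=[probs[c] for c in cats])

    motion = _draw(spec.motion_probs)
    ss = _draw(spec.ss_probs)
    hbond = _draw(spec.hbond_probs)
    burial = np.clip(np.round(rng.normal(spec.burial_mean, spec.burial_sd,
                                         size=n)), 0, None).astype(int)
    features = [
        ResidueFeatures(chain=chain, residue=i + 2, aa="A",
                        burial=int(burial[i]), ss=str(ss[i]),
                        hbond=str(hbond[i]),
                        hbond_count=0 if hbond[i] == "no" else 1,
                        motion=str(motion[i]))
        for i in range(n)
    ]
    linear = np.array([
        sum(coeffs[t].estimate * v for t, v in design_row(f).items()
            if coeffs[t].retained)
        for f in features
    ])
    noise = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    log_pf = linear + noise
    table = pd.DataFrame({
        "chain": chain,
        "residue": [f.residue for f in features],
        "aa": "A",
        "logpf_measured": log_pf,
        "motion_category": motion,
        "burial": burial,
        "hbond_category": hbond,
        "ss_category": ss,
    })
    return table, features


def train_test_split(table: pd.DataFrame, n_test: int, seed: int
                     ) -> pd.DataFrame:
    """Label rows 'train'/'test' with a reproducible random split."""
    if not 0 < n_test < len(table):
        raise ValueError("n_test must be in (0, n_rows)")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=n_test, replace=False)
    out = table.copy()
    out["set_label"] = "train"
    out.iloc[idx, out.columns.get_loc("set_label")] = "test"
    return out
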