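"""Protection-factor predictors.

Three routes from structure to protection factors:

1. **POPPeT** — a log-linear model of the base-10 logPF on categorical
   structural covariates (HX-enabling motion, secondary structure,
   hydrogen-bond acceptor type) and burial:

   .. math::

       \\mathrm{logPF} = \\beta_0 + \\beta_1 UD + \\beta_2 EX1
           + \\beta_3 (UD{+}EX1) + \\beta_4 helix + \\beta_5 \\beta\\text{-sheet}
           + \\beta_6 burial + \\beta_7..\\beta_9 (\\text{H-bond}) + \\varepsilon

   with reference levels motion=L, SS=no, H-bond=no and
   :math:`\\varepsilon \\sim N(0, \\sigma^2)`.  Fitting is ordinary least
   squares with backward elimination at p < 0.05; the published coefficient
   set ships as the preset ``"poppet-2018"``.
2. **Phenomenological approximation** —
   :math:`\\ln PF_i = \\beta_H N_i^H + \\beta_C N_i^C` with the two published
   coefficient pairs (all-atoms and backbone-only presets).
3. **COREX aggregation** — Boltzmann-weighted probabilities over a supplied
   ensemble of partially unfolded microstates; the PF of a residue is the
   probability ratio of states in which it is folded/buried versus
   unfolded/exposed.  Ensemble *generation* is out of scope: microstates are
   consumed as input.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import logsumexp

from .features import ResidueFeatures
from .kinetics import INFINITE_PROTECTION, LN10, R_KCAL

__all__ = [
    "Coefficient",
    "CoefficientSet",
    "PhenomenologicalParams",
    "PHENOM_ALL_ATOMS",
    "PHENOM_BACKBONE",
    "Microstate",
    "MissingCovariateError",
    "POPPET_TERMS",
    "design_row",
    "poppet_predict",
    "poppet_fit",
    "phenomenological_logpf",
    "microstate_probabilities",
    "corex_pf",
    "get_preset",
]

# model terms in canonical order; grouped into categorical factors for
# factor-wise backward elimination
POPPET_TERMS = (
    "intercept",
    "motion[UD]", "motion[EX1]", "motion[UD+EX1]",
    "ss[helix]", "ss[beta-sheet]",
    "burial",
    "hbond[H2O]", "hbond[mainchain-O]", "hbond[sidechain-O]",
)

FACTORS: dict[str, tuple[str, ...]] = {
    "motion": ("motion[UD]", "motion[EX1]", "motion[UD+EX1]"),
    "ss": ("ss[helix]", "ss[beta-sheet]"),
    "burial": ("burial",),
    "hbond": ("hbond[H2O]", "hbond[mainchain-O]", "hbond[sidechain-O]"),
}

_HBOND_TERM = {
    "Hbond-with-H2O": "hbond[H2O]",
    "Hbond-with-mainchain-O": "hbond[mainchain-O]",
    "Hbond-with-sidechain-O": "hbond[sidechain-O]",
}


class MissingCovariateError(ValueError):
    """A required covariate (e.g. the motion category) is unset."""


@dataclass
class Coefficient:
    estimate: float
    se: float | None = None
    p: float | None = None
    retained: bool = True


@dataclass
class CoefficientSet:
    """Fitted or published coefficients of the log-linear PF model."""

    coefficients: dict[str, Coefficient]
    sigma2: float | None = None       # residual variance on the logPF scale
    adj_r2: float | None = None
    n_train: int | None = None
    name: str = "custom"

    def __post_init__(self):
        if self.sigma2 is not None and self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        for term, c in self.coefficients.items():
            if c.retained and term != "intercept" and c.p is None:
                raise ValueError(f"retained term {term!r} lacks a p-value")

    def __getitem__(self, term: str) -> Coefficient:
        return self.coefficients[term]

    @property
    def sigma(self) -> float | None:
        return None if self.sigma2 is None else math.sqrt(self.sigma2)

    # -- JSON interchange ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "name": self.name,
            "sigma2": self.sigma2,
            "adj_r2": self.adj_r2,
            "n_train": self.n_train,
            "coefficients": [
                {"term": t, "estimate": c.estimate, "se": c.se, "p": c.p,
                 "retained": c.retained}
                for t, c in self.coefficients.items()
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CoefficientSet":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        payload = json.loads(text)
        coeffs = {
            d["term"]: Coefficient(d["estimate"], d.get("se"), d.get("p"),
                                   d.get("retained", True))
            for d in payload["coefficients"]
        }
        return cls(coefficients=coeffs, sigma2=payload.get("sigma2"),
                   adj_r2=payload.get("adj_r2"),
                   n_train=payload.get("n_train"),
                   name=payload.get("name", "custom"))


def _poppet_2018() -> CoefficientSet:
    # Published fit to the 30-hydrogen staphylococcal nuclease training set;
    # hydrogen-bond terms were not significant and are not part of the model.
    c = {
        "intercept": Coefficient(2.19940, 0.59566, 0.00120),
        "motion[UD]": Coefficient(1.63431, 0.22449, 2.08e-7),
        "motion[EX1]": Coefficient(2.12078, 0.19786, 2.03e-10),
        "motion[UD+EX1]": Coefficient(2.15429, 0.18957, 6.50e-11),
        "ss[helix]": Coefficient(0.59534, 0.19881, 0.00647),
        "ss[beta-sheet]": Coefficient(0.35710, 0.18679, 0.06844),
        "burial": Coefficient(0.04371, 0.01164, 0.00103),
        "hbond[H2O]": Coefficient(0.0, None, None, retained=False),
        "hbond[mainchain-O]": Coefficient(0.0, None, None, retained=False),
        "hbond[sidechain-O]": Coefficient(0.0, None, None, retained=False),
    }
    return CoefficientSet(coefficients=c, n_train=30, name="poppet-2018")


_PRESETS = {"poppet-2018": _poppet_2018}


def get_preset(name: str) -> CoefficientSet:
    """Return a named published coefficient set (``"poppet-2018"``)."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(_PRESETS)}") from None


# ---------------------------------------------------------------------------
# POPPeT prediction and fitting
# ---------------------------------------------------------------------------

def design_row(f: ResidueFeatures) -> dict[str, float]:
    """Indicator-coded covariate row of the full log-linear design."""
    if f.motion is None:
        raise MissingCovariateError(
            f"residue {f.chain}/{f.residue}: motion category is unset")
    row = dict.fromkeys(POPPET_TERMS, 0.0)
    row["intercept"] = 1.0
    if f.motion != "L":
        row[f"motion[{f.motion}]"] = 1.0
    if f.ss != "no":
        row[f"ss[{f.ss}]"] = 1.0
    row["burial"] = float(f.burial)
    if f.hbond != "no":
        row[_HBOND_TERM[f.hbond]] = 1.0
    return row


def poppet_predict(features: ResidueFeatures | Iterable[ResidueFeatures],
                   coeffs: CoefficientSet) -> float | np.ndarray:
    """Predicted logPF (base 10); dropped terms contribute zero."""
    if isinstance(features, ResidueFeatures):
        row = design_row(features)
        return float(sum(coeffs[t].estimate * v
                         for t, v in row.items()
                         if t in coeffs.coefficients and coeffs[t].retained))
    return np.array([poppet_predict(f, coeffs) for f in features])


def poppet_fit(training: Sequence[tuple[ResidueFeatures, float]],
               alpha: float = 0.05,
               elimination: str = "factor-wise") -> CoefficientSet:
    """Fit the log-linear PF model by OLS with backward elimination.

    ``elimination="factor-wise"`` (default) removes whole categorical
    factors: a factor is retained as long as any of its levels is
    significant at ``alpha``, and the factor whose most-significant level
    has the largest p-value is dropped first.  ``"term-wise"`` removes
    single columns.  Eliminated terms are reported with their last fitted
    estimate/p but flagged ``retained=False`` (they contribute zero to
    prediction).

    Columns with no variation (e.g. a category never observed) are dropped
    from the design before fitting and reported via a warning.
    """
    if elimination not in ("factor-wise", "term-wise"):
        raise ValueError("elimination must be 'factor-wise' or 'term-wise'")
    rows = [design_row(f) for f, _ in training]
    y = np.array([v for _, v in training], float)
    terms = [t for t in POPPET_TERMS]
    X = np.array([[r[t] for t in terms] for r in rows], float)

    # drop constant (all-equal) columns other than the intercept
    keep, dropped_rank = [], []
    for j, t in enumerate(terms):
        if t != "intercept" and np.ptp(X[:, j]) == 0.0:
            dropped_rank.append(t)
        else:
            keep.append(j)
    if dropped_rank:
        warnings.warn("dropped constant design columns before fitting: "
                      + ", ".join(dropped_rank))
    terms = [terms[j] for j in keep]
    X = X[:, keep]
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more training rows ({X.shape[0]}) than candidate terms "
            f"({X.shape[1]})")

    last_seen: dict[str, Coefficient] = {}
    active = list(terms)

    def _fit(cols: list[str]):
        idx = [terms.index(t) for t in cols]
        return sm.OLS(y, X[:, idx]).fit(), cols

    while True:
        res, cols = _fit(active)
        for t, est, se, p in zip(cols, res.params, res.bse, res.pvalues):
            last_seen[t] = Coefficient(float(est), float(se), float(p))
        candidates = [t for t in cols if t != "intercept"]
        if not candidates:
            break
        if elimination == "term-wise":
            worst = max(candidates, key=lambda t: last_seen[t].p)
            if last_seen[worst].p < alpha:
                break
            active = [t for t in active if t != worst]
        else:
            # factor-wise: score each factor by its most significant level
            fac_p = {}
            for fac, members in FACTORS.items():
                present = [t for t in members if t in cols]
                if present:
                    fac_p[fac] = min(last_seen[t].p for t in present)
            worst_fac = max(fac_p, key=fac_p.get)
            if fac_p[worst_fac] < alpha:
                break
            active = [t for t in active if t not in FACTORS[worst_fac]]
        if len(active) <= 1:  # only the intercept left
            res, cols = _fit(active)
            for t, est, se, p in zip(cols, res.params, res.bse, res.pvalues):
                last_seen[t] = Coefficient(float(est), float(se), float(p))
            break

    final_terms = set(cols)
    coeffs: dict[str, Coefficient] = {}
    for t in POPPET_TERMS:
        if t in final_terms:
            coeffs[t] = last_seen[t]
        elif t in last_seen:
            c = last_seen[t]
            coeffs[t] = Coefficient(c.estimate, c.se, c.p, retained=False)
        else:
            coeffs[t] = Coefficient(0.0, None, None, retained=False)
    return CoefficientSet(
        coefficients=coeffs,
        sigma2=float(res.mse_resid),
        adj_r2=float(res.rsquared_adj),
        n_train=len(y),
        name="fitted",
    )


# ---------------------------------------------------------------------------
# Phenomenological approximation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenomenologicalParams:
    """Coefficients of ``ln PF = beta_H N_H + beta_C N_C``."""

    beta_h: float
    beta_c: float
    mode: str = "all-atoms"


#: Published calibration counting all heavy atoms within 6.5 A.
PHENOM_ALL_ATOMS = PhenomenologicalParams(beta_h=2.0, beta_c=0.35,
                                          mode="all-atoms")
#: Published calibration counting backbone heavy atoms only.
PHENOM_BACKBONE = PhenomenologicalParams(beta_h=5.0, beta_c=1.0,
                                         mode="backbone-only")


def phenomenological_logpf(n_h: int, n_c: int,
                           params: PhenomenologicalParams = PHENOM_ALL_ATOMS,
                           assume_log10: bool = False) -> float:
    """logPF (base 10) from H-bond count ``N_H`` and burial ``N_C``.

    The published relation is on the natural-log scale and is divided by
    ln 10 at this interface; ``assume_log10`` reproduces a literal base-10
    reading of the coefficients instead.
    """
    if n_h < 0 or n_c < 0:
        raise ValueError("counts must be non-negative")
    ln_pf = params.beta_h * n_h + params.beta_c * n_c
    return ln_pf if assume_log10 else ln_pf / LN10


# ---------------------------------------------------------------------------
# COREX-style ensemble aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Microstate:
    """One partially unfolded state of the ensemble.

    ``folded`` and ``exposed`` map residue keys to flags; ``dg`` is the
    state's Gibbs free energy relative to an arbitrary reference (kcal/mol)
    — probabilities are invariant to a common shift.
    """

    state_id: str
    dg: float
    folded: Mapping
    exposed: Mapping


def microstate_probabilities(ensemble: Sequence[Microstate],
                             temperature: float = 293.15) -> np.ndarray:
    """Boltzmann probabilities of the microstates (log-sum-exp stabilised)."""
    if len(ensemble) < 2:
        raise ValueError("need at least 2 microstates")
    dg = np.array([s.dg for s in ensemble], float)
    if not np.all(np.isfinite(dg)):
        raise ValueError("non-finite microstate free energies")
    log_w = -dg / (R_KCAL * temperature)
    probs = np.exp(log_w - logsumexp(log_w))
    return probs / probs.sum()


def corex_pf(ensemble: Sequence[Microstate], residue_key,
             temperature: float = 293.15, pr_i: float = 0.0) -> float:
    """Ensemble-aggregated protection factor of one residue.

    ``PF_i`` is the ratio of summed probabilities of microstates in which
    the residue is folded and not solvent-exposed to those in which it is
    unfolded and exposed, each reduced by ``pr_i`` (the probability that
    the residue is natively accessible or becomes accessible through
    unfolding of others — supplied by the ensemble generator; defaults to 0
    with a warning when unspecified, as it is not computable from the
    ensemble flags alone).
    """
    probs = microstate_probabilities(ensemble, temperature)
    num = den = 0.0
    for s, p in zip(ensemble, probs):
        if residue_key not in s.folded or residue_key not in s.exposed:
            raise KeyError(f"microstate {s.state_id}: no flags for residue "
                           f"{residue_key!r}")
        if s.folded[residue_key] and not s.exposed[residue_key]:
            num += p
        elif not s.folded[residue_key] and s.exposed[residue_key]:
            den += p
    if pr_i == 0.0:
        warnings.warn("Pr(i) not supplied; assuming 0", stacklevel=2)
    num -= pr_i
    den -= pr_i
    if den <= 0.0:
        warnings.warn(f"residue {residue_key!r}: non-positive denominator; "
                      "returning infinite protection", stacklevel=2)
        return INFINITE_PROTECTION
    return num / den
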