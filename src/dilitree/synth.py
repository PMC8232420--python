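"""Synthetic drug cohorts with the statistical structure the screening
analysis assumes, so every pipeline stage is testable without external data.

The default cohort reproduces the published operating point of the
AMW >= 7.4 screen: class sizes 432:220, class-conditional AMW means
7.99 / 7.49, and tail probabilities P(AMW >= 7.4) of 0.64 (DILI) and 0.29
(no-DILI).  A symmetric distribution cannot satisfy mean 7.49 with 71% of
mass below 7.4, so the default family is a shifted log-normal whose
(mu, sigma) are solved in closed form from the mean and the tail
probability.  All randomness flows from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .chem.composition import Composition, amw as composition_amw
from .chem.masses import MassTable
from .chem.records import DiliClass, DrugRecord

__all__ = [
    "AmwDist",
    "MlogpDist",
    "AtcCategorySpec",
    "GeneratorSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_formulas",
    "DEFAULT_ATC_SPEC",
]


@dataclass(frozen=True)
class AmwDist:
    """Class-conditional AMW distribution.

    ``shifted-lognormal``: ``shift + LogNormal(mu, sigma)`` with mu/sigma
    calibrated so the distribution has the requested mean and
    ``P(X >= threshold) = frac_ge``.  ``normal``: plain Normal(mean, sd)
    (used by recovery tests, where the Bayes boundary is tractable).
    """

    family: str = "shifted-lognormal"
    mean: float = 7.99
    frac_ge: float | None = 0.64
    sd: float | None = None
    shift: float = 4.0
    threshold: float = 7.4

    def lognormal_params(self) -> tuple[float, float]:
        if self.family != "shifted-lognormal":
            raise ValueError("lognormal_params only applies to shifted-lognormal")
        if self.frac_ge is None or not (0.0 < self.frac_ge < 1.0):
            raise ValueError("frac_ge must be in (0, 1)")
        m = self.mean - self.shift
        t = self.threshold - self.shift
        if t <= 0 or m <= t:
            raise ValueError(
                "calibration requires shift < threshold < mean "
                f"(shift={self.shift}, threshold={self.threshold}, mean={self.mean})"
            )
        z = stats.norm.ppf(1.0 - self.frac_ge)
        # sigma solves 0.5*s^2 - z*s - ln(m/t) = 0 (positive root)
        sigma = z + math.sqrt(z * z + 2.0 * math.log(m / t))
        mu = math.log(t) - z * sigma
        return mu, sigma

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "shifted-lognormal":
            mu, sigma = self.lognormal_params()
            return self.shift + rng.lognormal(mu, sigma, size=n)
        if self.family == "normal":
            if self.sd is None or self.sd <= 0:
                raise ValueError("normal family requires sd > 0")
            return rng.normal(self.mean, self.sd, size=n)
        raise ValueError(f"unknown AMW family {self.family!r}")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        if self.family == "shifted-lognormal":
            mu, sigma = self.lognormal_params()
            return stats.lognorm.pdf(np.asarray(x) - self.shift, s=sigma,
                                     scale=math.exp(mu))
        if self.family == "normal":
            return stats.norm.pdf(x, loc=self.mean, scale=self.sd)
        raise ValueError(f"unknown AMW family {self.family!r}")

    def prob_ge(self, x: float) -> float:
        """P(X >= x) under the calibrated distribution."""
        if self.family == "shifted-lognormal":
            mu, sigma = self.lognormal_params()
            if x <= self.shift:
                return 1.0
            return float(
                stats.lognorm.sf(x - self.shift, s=sigma, scale=math.exp(mu))
            )
        return float(stats.norm.sf(x, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class MlogpDist:
    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=n)


@dataclass(frozen=True)
class AtcCategorySpec:
    """One first-level category: membership probabilities per class and a
    separability multiplier.  With separability s, members are sampled with
    weight exp(+s*(AMW-thr)) among DILI drugs and exp(-s*(AMW-thr)) among
    no-DILI drugs, so large s makes the threshold screen look good within
    the category without distorting the marginal AMW distributions."""

    code: str
    p_dili: float = 0.10
    p_nodili: float = 0.10
    separability: float = 0.0


DEFAULT_ATC_SPEC: tuple[AtcCategorySpec, ...] = (
    # high-separability categories
    AtcCategorySpec("B", 0.08, 0.10, 2.5),
    AtcCategorySpec("J", 0.14, 0.08, 2.5),
    AtcCategorySpec("M", 0.09, 0.08, 2.5),
    AtcCategorySpec("S", 0.08, 0.12, 2.5),
    # intermediate
    AtcCategorySpec("A", 0.12, 0.18, 0.8),
    AtcCategorySpec("N", 0.18, 0.22, 0.8),
    # low-separability categories
    AtcCategorySpec("C", 0.15, 0.15, 0.0),
    AtcCategorySpec("G", 0.06, 0.08, 0.0),
    AtcCategorySpec("R", 0.05, 0.14, 0.0),
    AtcCategorySpec("V", 0.02, 0.09, 0.0),
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Full parameterization of a synthetic cohort; the seed determines the
    output completely."""

    n_dili: int = 432
    n_nodili: int = 220
    amw_dili: AmwDist = field(default_factory=lambda: AmwDist(mean=7.99, frac_ge=0.64))
    # shift 6.5 keeps the right-skew mild enough for stable sample means
    # while preserving the exact mean/operating-point calibration
    amw_nodili: AmwDist = field(
        default_factory=lambda: AmwDist(mean=7.49, frac_ge=0.29, shift=6.5)
    )
    mlogp_dili: MlogpDist = MlogpDist(2.6, 1.3)
    mlogp_nodili: MlogpDist = MlogpDist(0.9, 1.6)
    n_noise_features: int = 3
    noise_correlation: float = 0.0
    atc_spec: tuple[AtcCategorySpec, ...] = DEFAULT_ATC_SPEC
    subclass_split: float = 175.0 / 432.0  # fraction Most within DILI
    subclass_shift: float = 0.75           # AMW weight for Most selection
    year_range: tuple[int, int] = (2010, 2019)
    threshold: float = 7.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dili < 0 or self.n_nodili < 0:
            raise ValueError("class sizes must be non-negative")
        if not (0.0 <= self.subclass_split <= 1.0):
            raise ValueError("subclass_split must be in [0, 1]")
        if not (0.0 <= self.noise_correlation < 1.0):
            raise ValueError("noise_correlation must be in [0, 1)")


@dataclass
class SyntheticCohort:
    records: list[DrugRecord]
    features: pd.DataFrame       # index: drug id; columns AMW, MLOGP, NOISE_*
    labels: np.ndarray           # 1 = DILI, 0 = no-DILI
    ground_truth: dict

    @property
    def ids(self) -> list[str]:
        return list(self.features.index)


def _bayes_boundary(spec: GeneratorSpec) -> float | None:
    """Prior-weighted density crossing of the two AMW distributions nearest
    the screening threshold (None when no bracketed crossing is found)."""
    n = spec.n_dili + spec.n_nodili
    if spec.n_dili == 0 or spec.n_nodili == 0:
        return None
    pi_pos = spec.n_dili / n
    pi_neg = spec.n_nodili / n

    def diff(x: float) -> float:
        return float(
            pi_pos * spec.amw_dili.pdf(np.array([x]))[0]
            - pi_neg * spec.amw_nodili.pdf(np.array([x]))[0]
        )

    grid = np.linspace(spec.threshold - 4.0, spec.threshold + 4.0, 801)
    vals = [diff(x) for x in grid]
    crossings = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            crossings.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            crossings.append(
                optimize.brentq(diff, grid[i], grid[i + 1], xtol=1e-10)
            )
    if not crossings:
        return None
    return float(min(crossings, key=lambda c: abs(c - spec.threshold)))


def _weighted_subset(
    rng: np.random.Generator, idx: np.ndarray, size: int, log_weights: np.ndarray
) -> np.ndarray:
    if size <= 0 or idx.size == 0:
        return np.array([], dtype=int)
    size = min(size, idx.size)
    w = np.exp(log_weights - log_weights.max())
    p = w / w.sum()
    return rng.choice(idx, size=size, replace=False, p=p)


def generate_cohort(spec: GeneratorSpec) -> SyntheticCohort:
    """Draw a cohort of labeled drugs and their descriptor table.

    Per-drug AMW comes from the class-conditional distribution, the
    lipophilicity feature from a class-conditional normal, noise features
    are class-independent (optionally equicorrelated), Most/Less subclasses
    and ATC categories are assigned by AMW-weighted sampling, and the
    generating parameters (including the Bayes boundary of the AMW densities
    and the expected operating point of the threshold screen) are emitted
    for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed)]))
    n_pos, n_neg = spec.n_dili, spec.n_nodili
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("empty cohort")

    labels = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    amw = np.r_[
        spec.amw_dili.sample(rng, n_pos), spec.amw_nodili.sample(rng, n_neg)
    ]
    mlogp = np.r_[
        spec.mlogp_dili.sample(rng, n_pos), spec.mlogp_nodili.sample(rng, n_neg)
    ]
    if not np.isfinite(amw).all() or not np.isfinite(mlogp).all():
        raise ValueError("distribution parameters produced non-finite values")

    columns: dict[str, np.ndarray] = {"AMW": amw, "MLOGP": mlogp}
    if spec.n_noise_features > 0:
        rho = spec.noise_correlation
        shared = rng.standard_normal(n)
        for j in range(spec.n_noise_features):
            eps = rng.standard_normal(n)
            columns[f"NOISE_{j + 1:02d}"] = (
                math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * eps
            )

    # Most/Less subclasses: Most drawn with weight exp(delta*(AMW - thr)) so
    # the >= threshold odds ratio Most:Less exceeds 1 without changing the
    # DILI-marginal AMW distribution.
    dili_idx = np.nonzero(labels == 1)[0]
    n_most = int(round(spec.subclass_split * n_pos))
    most_idx = set(
        _weighted_subset(
            rng,
            dili_idx,
            n_most,
            spec.subclass_shift * (amw[dili_idx] - spec.threshold),
        ).tolist()
    )

    # ATC categories, independently per category.
    nodili_idx = np.nonzero(labels == 0)[0]
    atc_assign: dict[int, list[str]] = {i: [] for i in range(n)}
    for cat in spec.atc_spec:
        for cls_idx, p, sign in (
            (dili_idx, cat.p_dili, +1.0),
            (nodili_idx, cat.p_nodili, -1.0),
        ):
            count = int(round(p * cls_idx.size))
            chosen = _weighted_subset(
                rng,
                cls_idx,
                count,
                sign * cat.separability * (amw[cls_idx] - spec.threshold),
            )
            for i in chosen:
                atc_assign[int(i)].append(cat.code)

    years = rng.integers(spec.year_range[0], spec.year_range[1] + 1, size=n)

    ids = [f"SYN{i + 1:05d}" for i in range(n)]
    records = []
    for i in range(n):
        if labels[i] == 1:
            cls = DiliClass.MOST if i in most_idx else DiliClass.LESS
        else:
            cls = DiliClass.NO
        records.append(
            DrugRecord(
                id=ids[i],
                name=ids[i],
                dili_class=cls,
                atc_codes=sorted(atc_assign[i]),
                year=int(years[i]),
            )
        )

    features = pd.DataFrame(columns, index=pd.Index(ids, name="id"))
    ground_truth = {
        "seed": spec.seed,
        "n_dili": n_pos,
        "n_nodili": n_neg,
        "threshold": spec.threshold,
        "amw_dili": asdict(spec.amw_dili),
        "amw_nodili": asdict(spec.amw_nodili),
        "mlogp_dili": asdict(spec.mlogp_dili),
        "mlogp_nodili": asdict(spec.mlogp_nodili),
        "expected_sensitivity": spec.amw_dili.prob_ge(spec.threshold)
        if n_pos
        else None,
        "expected_specificity": 1.0 - spec.amw_nodili.prob_ge(spec.threshold)
        if n_neg
        else None,
        "bayes_boundary": _bayes_boundary(spec),
        "subclass_split": spec.subclass_split,
        "subclass_shift": spec.subclass_shift,
        "atc_spec": [asdict(c) for c in spec.atc_spec],
        "n_noise_features": spec.n_noise_features,
        "noise_correlation": spec.noise_correlation,
    }
    return SyntheticCohort(
        records=records, features=features, labels=labels, ground_truth=ground_truth
    )


_FORMULA_ELEMENT_RANGES = (
    ("C", 1, 20),
    ("H", 0, 40),
    ("N", 0, 4),
    ("O", 0, 6),
    ("S", 0, 2),
    ("F", 0, 4),
    ("Cl", 0, 3),
    ("Br", 0, 2),
)


def generate_formulas(
    n: int,
    target_amw_range: tuple[float, float],
    seed: int = 0,
    masses: MassTable | None = None,
    max_attempts_per_formula: int = 20000,
) -> list[str]:
    """Random molecular formulas over {C,H,N,O,S,F,Cl,Br} whose average mass
    per atom lies in ``target_amw_range`` (rejection sampling against the
    same mass table the descriptor pipeline uses)."""
    lo, hi = target_amw_range
    table = masses if masses is not None else MassTable.default()
    if hi < lo:
        raise ValueError("empty target range")
    max_mass = max(table.mass(sym) for sym, _, _ in _FORMULA_ELEMENT_RANGES)
    if hi < table.mass("H") or lo > max_mass:
        raise ValueError(
            f"target range [{lo}, {hi}] is unattainable with elements "
            "C,H,N,O,S,F,Cl,Br"
        )
    if n == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    out: list[str] = []
    attempts = 0
    budget = max_attempts_per_formula * n
    while len(out) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not find {n} formulas with AMW in [{lo}, {hi}] after "
                f"{attempts} attempts"
            )
        attempts += 1
        counts = {}
        for sym, low, high in _FORMULA_ELEMENT_RANGES:
            c = int(rng.integers(low, high + 1))
            if c:
                counts[sym] = c
        if "C" in counts:
            # keep hydrogen counts loosely tied to carbon skeleton size
            counts["H"] = min(counts.get("H", 0), 2 * counts["C"] + 2)
            if counts["H"] == 0:
                counts.pop("H", None)
        if not counts:
            continue
        comp = Composition(counts)
        if lo <= composition_amw(comp, table) <= hi:
            out.append(comp.hill_formula())
    return out
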