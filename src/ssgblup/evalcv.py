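"""Joint-reference-population cross-validation.

Implements the gradient-grouping experiment: the target breed's genotyped
animals form the base reference; other-breed genotyped animals are added in
nested random increments (e.g. 0, 300, ..., 2,100), and for each scenario
the model is run twice — with all phenotypes ("full") and with the
validation animals' phenotype records masked ("reduced").  The full-data
GEBV plays the role of the proxy true breeding value TBV*; reliability is
the Pearson correlation Cor(TBV*, reduced GEBV), and the regression
TBV* = b0 + b1 GEBV gives the estimation bias b0 and inflation coefficient
b1 (b1 < 1 means over-dispersed predictions).

TBV* is a *proxy*: it is itself an estimate, so these reliabilities measure
the information lost by masking, not accuracy against truth.  When a
simulation's true breeding values are available they can be passed as the
reference instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .model import GibbsConfig, SingleStepGBLUP

REPORT_COLUMNS = ["scenario_size", "breed", "trait", "population", "R", "R2", "b0", "b1"]


def gradient_groups(pool_ids, base_ids, step: int = 300, max_added: int | None = None,
                    seed: int = 0, nested: bool = True):
    """Nested random reference sets of sizes |base|, |base|+step, ...

    The other-breed pool is shuffled once and prefixes of length 0, step,
    2*step, ... are appended to ``base_ids``, so each scenario extends the
    previous one and scenario curves differ only by the animals added.
    ``nested=False`` redraws each subset independently.
    """
    pool = list(pool_ids)
    if max_added is None:
        max_added = (len(pool) // step) * step
    if step <= 0:
        raise ValueError("step must be positive")
    if max_added > len(pool):
        raise ValueError(f"pool has {len(pool)} animals, cannot add {max_added}")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(pool, dtype=object)[rng.permutation(len(pool))])
    sets = []
    for k in range(0, max_added + 1, step):
        if nested:
            added = shuffled[:k]
        else:
            added = list(np.array(pool, dtype=object)[rng.permutation(len(pool))[:k]])
        sets.append(list(base_ids) + added)
    return sets


def select_validation(genotyped_target_ids, pedigree: pd.DataFrame, n: int = 50,
                      window_years: int = 4):
    """The n youngest genotyped target-breed animals born within the recent window.

    Eligible animals are those born within ``window_years`` of the latest
    birth year among the candidates; the ``n`` youngest are taken, ties
    broken by identifier order.
    """
    ped = pedigree.set_index("animal")
    cand = [a for a in genotyped_target_ids if a in ped.index]
    if not cand:
        raise ValueError("no genotyped target animals found in the pedigree")
    years = ped.loc[cand, "birth_year"].astype(int)
    latest = int(years.max())
    eligible = [a for a in cand if years[a] > latest - window_years]
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} animals born in the last "
                         f"{window_years} years; need {n} (short by {n - len(eligible)})")
    eligible.sort(key=lambda a: (-int(years[a]), a))
    return eligible[:n]


@dataclass
class DataBundle:
    """The linked inputs of one evaluation experiment."""

    pedigree: pd.DataFrame
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    target_breed: str
    other_breed: str
    trait_of_breed: dict  # breed label -> trait name


@dataclass
class ScenarioResult:
    reference_ids: list
    validation_ids: list
    gebv_full: pd.DataFrame
    gebv_reduced: pd.DataFrame
    vc_full: object
    vc_reduced: object
    h2_full: np.ndarray
    h2_reduced: np.ndarray


def run_scenario(reference_ids, validation_ids, data: DataBundle,
                 gibbs: GibbsConfig, blend_weight: float = 0.05) -> ScenarioResult:
    """One full/reduced pair of evaluations sharing the scenario's H matrix.

    The genotyped set is reference + validation; phenotypes are restricted
    to target-breed records plus the records of other-breed animals inside
    the reference; the reduced run additionally masks the validation
    animals' records (their genotypes and pedigree links remain).
    """
    validation_ids = list(validation_ids)
    bad = [a for a in validation_ids
           if data.genotypes.breed_of(a) != data.target_breed]
    if bad:
        raise ValueError(f"validation animals must be genotyped {data.target_breed}: {bad[:5]}")
    genotyped = list(dict.fromkeys(list(reference_ids) + validation_ids))
    ref_set = set(reference_ids) | set(validation_ids)
    pt = data.phenotypes
    is_target = pt["breed"] == data.target_breed
    keep_full = is_target | pt["animal"].isin(ref_set)
    pt_full = pt.loc[keep_full].reset_index(drop=True)
    pt_reduced = pt_full.loc[~pt_full["animal"].isin(validation_ids)].reset_index(drop=True)
    for factor in ("farm", "year_class", "season", "parity"):
        gone = set(pt_full[factor]) - set(pt_reduced[factor])
        if gone:
            warnings.warn(f"masking the validation group empties {factor} level(s) "
                          f"{sorted(map(str, gone))}; dropped from the reduced model",
                          stacklevel=2)

    traits = (data.trait_of_breed[data.target_breed],
              data.trait_of_breed[data.other_breed])

    def _fit(p):
        est = SingleStepGBLUP(traits=traits, blend_weight=blend_weight,
                              chain_length=gibbs.chain_length, burn_in=gibbs.burn_in,
                              thin=gibbs.thin, n_location_scans=gibbs.n_location_scans,
                              random_state=gibbs.seed)
        est.fit(p, pedigree=data.pedigree, genotypes=data.genotypes,
                genotyped_ids=genotyped)
        return est

    full = _fit(pt_full)
    reduced = _fit(pt_reduced)
    return ScenarioResult(
        reference_ids=list(reference_ids), validation_ids=validation_ids,
        gebv_full=full.gebv_, gebv_reduced=reduced.gebv_,
        vc_full=full.variance_components_, vc_reduced=reduced.variance_components_,
        h2_full=full.h2_, h2_reduced=reduced.h2_)


def reliability(tbv_star, gebv_reduced):
    """(R, R2): Pearson correlation and its square; NaN on zero variance."""
    x = np.asarray(tbv_star, dtype=float)
    y = np.asarray(gebv_reduced, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must align")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r


def bias_inflation(tbv_star, gebv_reduced):
    """OLS of TBV* on GEBV: intercept b0 (bias) and slope b1 (inflation)."""
    x = np.asarray(gebv_reduced, dtype=float)
    y = np.asarray(tbv_star, dtype=float)
    if x.var() == 0:
        raise ValueError("zero variance in GEBV; regression undefined")
    b1 = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    b0 = float(y.mean() - b1 * x.mean())
    return b0, b1


def run_validation_experiment(data: DataBundle, gibbs: GibbsConfig,
                              step: int = 300, max_added: int | None = None,
                              n_validation: int = 50, window_years: int = 4,
                              grouping_seed: int = 0,
                              blend_weight: float = 0.05):
    """The whole gradient experiment; returns (report, scenario_results).

    Report rows: scenario_size x trait x population in {total, validation},
    with R, R2, b0, b1 of reduced-run GEBVs against full-run GEBVs (TBV*).
    "Total" covers all genotyped target-breed animals, "validation" the
    masked subset.  Missing values (degenerate variance) are NaN.
    """
    gm = data.genotypes
    target_ids = [a for a, b in zip(gm.animal_ids, gm.breeds) if b == data.target_breed]
    other_ids = [a for a, b in zip(gm.animal_ids, gm.breeds) if b == data.other_breed]
    validation_ids = select_validation(target_ids, data.pedigree,
                                       n=n_validation, window_years=window_years)
    base_ids = [a for a in target_ids if a not in set(validation_ids)]
    references = gradient_groups(other_ids, base_ids, step=step,
                                 max_added=max_added, seed=grouping_seed)
    trait = data.trait_of_breed[data.target_breed]
    rows, results = [], []
    for ref in references:
        res = run_scenario(ref, validation_ids, data, gibbs, blend_weight)
        size = len(ref) + len(validation_ids)
        full = res.gebv_full.set_index("animal")[trait]
        red = res.gebv_reduced.set_index("animal")[trait]
        for population, idset in (("total", target_ids), ("validation", validation_ids)):
            tbv_star = full.loc[idset].to_numpy()
            gebv = red.loc[idset].to_numpy()
            r, r2 = reliability(tbv_star, gebv)
            if np.var(gebv) > 0:
                b0, b1 = bias_inflation(tbv_star, gebv)
            else:
                b0, b1 = float("nan"), float("nan")
            rows.append((size, data.target_breed, trait, population, r, r2, b0, b1))
        results.append(res)
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return report, results
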