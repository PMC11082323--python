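"""Two-breed synthetic data generator.

Emulates the structure of a joint dairy-cattle reference population: two
breeds with divergent allele frequencies (Balding-Nichols divergence at a
configurable Fst, so cross-breed genomic kinship is near zero), multi-
generation pedigrees per breed, genotypes gene-dropped along the pedigree
with Haldane recombination (which creates within-chromosome LD through
founder-pool drift), and lactation phenotypes built from a bivariate
breed-trait model: each breed's trait has its own mean and scale, breeding
values come from SNP effects shared across breeds and rescaled per breed to
reach a configured genetic correlation, and every animal is phenotyped only
for its own breed's trait (the breeds are reared in separate populations, so
there is no cross-breed residual covariance).

Fixed-effect structure mirrors routine milk-recording models: herd (farm),
calving-year class, calving season and parity, with per-breed level sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genio import (GenotypeMatrix, make_snp_map, write_plink_pedmap,
                    write_pedigree_csv, write_phenotype_csv, write_dosage_csv)

SEASONS = ("spring", "summer", "autumn", "winter")


@dataclass
class SimConfig:
    """Study-condition knobs for the two-breed generator.

    Defaults are the desk-scale analogue of a 485 + 2,100 head, 120K-marker
    chip study: 2 breeds x 500 animals over 3 generations, 3 chromosomes x
    1,000 SNPs, breed divergence Fst 0.1, per-breed-trait heritabilities
    0.30 / 0.25 with genetic correlation 0.5, and trait means/SDs on the
    scale gap seen between a dual-purpose and a specialist dairy breed.
    """

    n_animals_per_breed: int = 500
    n_generations: int = 3
    n_snps: int = 3000
    n_chromosomes: int = 3
    chrom_length_morgans: float = 1.0
    fst: float = 0.1
    ancestral_freq_range: tuple = (0.05, 0.95)
    h2: tuple = (0.30, 0.25)
    genetic_correlation: float = 0.5
    trait_means: tuple = (4126.0, 10117.0)
    trait_sds: tuple = (1406.0, 2045.0)
    fixed_effect_sd_frac: float = 0.15
    breeds: tuple = ("brown", "holstein")
    n_farms: int = 5
    base_year: int = 2000
    max_parity: int = 6
    mean_extra_lactations: float = 2.4
    seed: int = 20240426

    def validate(self) -> None:
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        for h in self.h2:
            if not (0 <= h < 1):
                raise ValueError("h2 must be in [0, 1)")
        if abs(self.genetic_correlation) > 1:
            raise ValueError("|genetic_correlation| must be <= 1")
        for name in ("n_animals_per_breed", "n_generations", "n_snps", "n_chromosomes", "n_farms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("ancestral_freq_range", "h2", "trait_means", "trait_sds", "breeds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth retained from a simulation for parameter-recovery tests."""

    tbv: pd.DataFrame          # animal, breed, tbv_trait1, tbv_trait2
    sigma_a2: tuple            # per breed-trait additive variance actually realized
    sigma_e2: tuple            # per breed-trait residual variance used
    sigma_a12: float           # realized cross-trait TBV covariance (all animals)
    genetic_correlation: float # realized cross-trait TBV correlation
    realized_fst: float

    def h2(self) -> tuple:
        return tuple(a / (a + e) if (a + e) > 0 else 0.0
                     for a, e in zip(self.sigma_a2, self.sigma_e2))


def hudson_fst(p1, p2) -> float:
    """Hudson-style ratio-of-averages Fst from two population frequency vectors."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def simulate_founder_frequencies(n_snps: int, fst: float, freq_range=(0.05, 0.95), seed: int = 0):
    """Per-breed allele frequencies under the Balding-Nichols model.

    Ancestral frequencies are uniform on ``freq_range``; each breed's
    frequency is Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst) around the ancestral
    p, or exactly p when Fst = 0.  Returns (freqs_breed1, freqs_breed2).
    """
    if not (0 <= fst < 1):
        raise ValueError("fst must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = freq_range
    p = rng.uniform(lo, hi, size=n_snps)
    if fst == 0:
        return p.copy(), p.copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    eps = 1e-4
    f1 = np.clip(rng.beta(a, b), eps, 1 - eps)
    f2 = np.clip(rng.beta(a, b), eps, 1 - eps)
    return f1, f2


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Two disjoint breed pedigrees in topological order.

    Animals are split as evenly as possible over ``n_generations`` cohorts;
    generation-0 animals are founders (parents "0"), later cohorts draw a
    sire and a dam uniformly (distinct) from the previous cohort of the same
    breed.  Birth year = base_year + generation.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    rows = []
    for b, breed in enumerate(config.breeds):
        n = config.n_animals_per_breed
        g = config.n_generations
        sizes = [n // g + (1 if i < n % g else 0) for i in range(g)]
        prev_gen: list[str] = []
        counter = 0
        for gen, size in enumerate(sizes):
            this_gen = []
            for _ in range(size):
                counter += 1
                aid = f"{breed}_{counter:05d}"
                if gen == 0 or len(prev_gen) < 2:
                    sire, dam = "0", "0"
                else:
                    sire, dam = rng.choice(len(prev_gen), size=2, replace=False)
                    sire, dam = prev_gen[sire], prev_gen[dam]
                rows.append((aid, sire, dam, breed, config.base_year + gen))
                this_gen.append(aid)
            prev_gen = this_gen
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "breed", "birth_year"])


def default_snp_map(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced SNPs: each chromosome spans 100 Mb mapped to chrom_length_morgans."""
    per = [config.n_snps // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_snps % config.n_chromosomes):
        per[i] += 1
    snp_ids, chroms, pos = [], [], []
    span = 100_000_000
    for c in range(config.n_chromosomes):
        spacing = span // (per[c] + 1)
        for j in range(per[c]):
            snp_ids.append(f"snp{c + 1}_{j + 1:05d}")
            chroms.append(c + 1)
            pos.append((j + 1) * spacing)
    return make_snp_map(snp_ids, chroms, pos)


def _genetic_positions(snp_map: pd.DataFrame, chrom_length_morgans: float):
    """Morgans proportional to bp within each chromosome (uniform map)."""
    out = {}
    for c, grp in snp_map.groupby("chromosome"):
        p = grp["position_bp"].to_numpy(dtype=float)
        span = max(p.max(), 1.0)
        out[c] = (grp.index.to_numpy(), p / span * chrom_length_morgans)
    return out


def _gamete(hap: np.ndarray, gpos_by_chrom, rng, length_morgans: float) -> np.ndarray:
    """One meiosis: Haldane crossovers (Poisson number, uniform positions), no interference."""
    gam = np.empty(hap.shape[1], dtype=np.int8)
    for _, (idx, gpos) in gpos_by_chrom.items():
        start = rng.integers(0, 2)
        k = rng.poisson(length_morgans)
        if k == 0:
            gam[idx] = hap[start, idx]
            continue
        xo = np.sort(rng.uniform(0.0, length_morgans, size=k))
        phase = (start + np.searchsorted(xo, gpos, side="right")) % 2
        gam[idx] = np.where(phase == 0, hap[0, idx], hap[1, idx])
    return gam


def drop_genotypes(pedigree: pd.DataFrame, founder_freqs: dict, snp_map: pd.DataFrame,
                   seed: int = 0, chrom_length_morgans: float = 1.0) -> GenotypeMatrix:
    """Gene-drop genotypes along the pedigree.

    Founder haplotypes are drawn site-wise from the founder's breed
    frequencies; descendants inherit one recombined gamete per parent.
    ``founder_freqs`` maps breed label -> coded-allele frequency vector.
    Animals must have either both parents known or none.
    """
    for c, grp in snp_map.groupby("chromosome"):
        if not np.all(np.diff(grp["position_bp"].to_numpy()) > 0):
            raise ValueError(f"map positions not strictly increasing on chromosome {c}")
    rng = np.random.default_rng(seed)
    m = len(snp_map)
    gpos = _genetic_positions(snp_map, chrom_length_morgans)
    haplos: dict[str, np.ndarray] = {}
    for row in pedigree.itertuples(index=False):
        known = (row.sire != "0") + (row.dam != "0")
        if known == 1:
            raise ValueError(f"animal {row.animal} has exactly one known parent; "
                             "the gene-dropper requires both-or-none")
        if known == 0:
            freqs = founder_freqs[row.breed]
            hap = (rng.random((2, m)) < freqs[None, :]).astype(np.int8)
        else:
            if row.sire not in haplos or row.dam not in haplos:
                raise ValueError(f"parents of {row.animal} not simulated before it "
                                 "(pedigree must be topologically ordered)")
            hap = np.stack([
                _gamete(haplos[row.sire], gpos, rng, chrom_length_morgans),
                _gamete(haplos[row.dam], gpos, rng, chrom_length_morgans),
            ])
        haplos[row.animal] = hap
    ids = pedigree["animal"].to_numpy()
    dosages = np.stack([haplos[a].sum(axis=0) for a in ids]).astype(float)
    return GenotypeMatrix(ids, dosages, pedigree["breed"].to_numpy())


def simulate_phenotypes(pedigree: pd.DataFrame, genotypes: GenotypeMatrix,
                        config: SimConfig, seed: int = 0):
    """Lactation phenotypes plus ground truth.

    TBVs for both breed-traits are built for *every* animal from shared SNP
    effects (effect vectors correlated at ``genetic_correlation``).  Effects
    are drawn iid and scaled deterministically so that the TBV vector is a
    draw from N(0, sigma_a2 G) with sigma_a2 = h2 x trait_sd^2 on the scale
    of the VanRaden G built from these genotypes — i.e. the additive
    variance stored as truth is the same estimand the animal model fits.

    Each animal gets one lactation record per parity (1 + a Poisson number
    of later lactations, capped at ``max_parity``), only for its own breed's
    trait: value = breed mean + farm + year-class + season + parity effects
    + TBV + record residual; residuals are independent within and across
    breeds.  Year classes follow the calving year (birth year + parity).
    """
    for h in config.h2:
        if h >= 1:
            raise ValueError("h2 = 1 requested; residual variance must be positive")
    config.validate()
    rng = np.random.default_rng(seed)
    m = genotypes.n_snps
    n = genotypes.n_animals
    freqs = genotypes.dosages.mean(axis=0) / 2.0
    Mc = genotypes.dosages - 2.0 * freqs[None, :]
    # Mc @ u with u ~ iid N(0, s2) is a draw from N(0, s2 * tau * G_vanraden)
    tau = 2.0 * float((freqs * (1 - freqs)).sum())

    r = config.genetic_correlation
    u1 = rng.normal(size=m)
    w = rng.normal(size=m)
    u2 = r * u1 + np.sqrt(max(0.0, 1 - r**2)) * w
    raw = np.column_stack([Mc @ u1, Mc @ u2])  # n x 2, both traits for all animals

    tbv = np.zeros_like(raw)
    sigma_a2, sigma_e2 = [], []
    for t in range(2):
        sa2 = config.h2[t] * config.trait_sds[t] ** 2
        se2 = (1 - config.h2[t]) * config.trait_sds[t] ** 2
        if config.h2[t] == 0 or tau == 0:
            tbv[:, t] = 0.0
            sa2 = 0.0
        else:
            tbv[:, t] = raw[:, t] * np.sqrt(sa2 / tau)
        sigma_a2.append(float(sa2))
        sigma_e2.append(float(se2))

    # per-breed fixed-effect level sets and their (drawn-once) effects
    pos = {a: i for i, a in enumerate(genotypes.animal_ids)}
    records = []
    for t, breed in enumerate(config.breeds):
        sub = pedigree[pedigree["breed"] == breed]
        eff_sd = config.fixed_effect_sd_frac * config.trait_sds[t]
        farms = [f"{breed}_farm{k + 1}" for k in range(config.n_farms)]
        years = sorted(sub["birth_year"].unique())
        farm_eff = dict(zip(farms, rng.normal(0, eff_sd, len(farms))))
        year_eff = dict(zip(years, rng.normal(0, eff_sd, len(years))))
        season_eff = dict(zip(SEASONS, rng.normal(0, eff_sd, len(SEASONS))))
        parity_eff = dict(zip(range(1, config.max_parity + 1),
                              rng.normal(0, eff_sd, config.max_parity)))
        for row in sub.itertuples(index=False):
            farm = farms[rng.integers(len(farms))]
            n_lact = 1 + min(int(rng.poisson(config.mean_extra_lactations)),
                             config.max_parity - 1)
            a = tbv[pos[row.animal], t]
            for parity in range(1, n_lact + 1):
                season = SEASONS[rng.integers(len(SEASONS))]
                # calving year grouped into 2-year classes: ungrouped calendar
                # year equals birth year + parity exactly, which would make the
                # year/parity dummies collinear (the classic year-parity
                # confound that milk-recording models break by grouping years)
                year = (int(row.birth_year) + parity) // 2 * 2
                if year not in year_eff:
                    year_eff[year] = rng.normal(0, eff_sd)
                e = rng.normal(0, np.sqrt(sigma_e2[t]))
                value = (config.trait_means[t] + farm_eff[farm] + year_eff[year]
                         + season_eff[season] + parity_eff[parity] + a + e)
                records.append((row.animal, breed, f"trait_{breed}", value,
                                farm, f"yc{year}", season, parity))
    pt = pd.DataFrame(records, columns=["animal", "breed", "trait", "value",
                                        "farm", "year_class", "season", "parity"])

    tbv_df = pd.DataFrame({
        "animal": genotypes.animal_ids,
        "breed": genotypes.breeds,
        "tbv_trait1": tbv[:, 0],
        "tbv_trait2": tbv[:, 1],
    })
    # realized (co)variances in the G-metric: for TBVs t = Mc w the quadratic
    # form t' G^-1 t equals tau * |w|^2, so the realized estimand of the
    # animal model (which sees a ~ N(0, G0 x H)) is S/n with S_ij = tau w_i.w_j;
    # the min-norm coefficients w recover the row-space projection of the
    # drawn effects
    if tau > 0 and np.abs(tbv).max() > 0:
        W, *_ = np.linalg.lstsq(Mc, tbv, rcond=None)
        S = tau * (W.T @ W)
        sigma_a2 = [float(S[0, 0] / n), float(S[1, 1] / n)]
        cov12 = float(S[0, 1] / n)
        denom = np.sqrt(S[0, 0] * S[1, 1])
        rg = float(S[0, 1] / denom) if denom > 0 else 0.0
        for t in range(2):
            if config.h2[t] == 0:
                sigma_a2[t] = 0.0
    else:
        rg, cov12 = 0.0, 0.0
    truth = TruthRecord(
        tbv=tbv_df,
        sigma_a2=tuple(sigma_a2),
        sigma_e2=tuple(sigma_e2),
        sigma_a12=cov12,
        genetic_correlation=rg,
        realized_fst=np.nan,
    )
    return pt, truth


def simulate_dataset(config: SimConfig):
    """Full simulation chain: frequencies -> pedigree -> genotypes -> phenotypes.

    All randomness derives from ``config.seed`` via named substreams, so the
    same config is byte-reproducible.  Returns (pedigree, genotypes, snp_map,
    phenotypes, truth).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(("freq", "ped", "drop", "pheno"), ss.spawn(4))}
    f1, f2 = simulate_founder_frequencies(config.n_snps, config.fst,
                                          config.ancestral_freq_range, seeds["freq"])
    ped = simulate_pedigree(config)
    snp_map = default_snp_map(config)
    gm = drop_genotypes(ped, {config.breeds[0]: f1, config.breeds[1]: f2},
                        snp_map, seeds["drop"], config.chrom_length_morgans)
    pt, truth = simulate_phenotypes(ped, gm, config, seeds["pheno"])
    truth.realized_fst = hudson_fst(f1, f2)
    return ped, gm, snp_map, pt, truth


def write_dataset(outdir, config: SimConfig) -> dict:
    """Simulate and write PED/MAP, pedigree/phenotype/truth CSVs and the config echo."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ped, gm, snp_map, pt, truth = simulate_dataset(config)
    write_plink_pedmap(gm, snp_map, out / "genotypes.ped", out / "genotypes.map")
    write_dosage_csv(gm, snp_map, out / "genotypes.csv")
    write_pedigree_csv(ped, out / "pedigree.csv")
    write_phenotype_csv(pt, out / "phenotypes.csv")
    truth.tbv.to_csv(out / "truth_tbv.csv", index=False)
    pd.DataFrame({
        "parameter": ["sigma_a2_trait1", "sigma_a2_trait2", "sigma_e2_trait1",
                      "sigma_e2_trait2", "sigma_a12", "genetic_correlation", "realized_fst"],
        "value": [truth.sigma_a2[0], truth.sigma_a2[1], truth.sigma_e2[0],
                  truth.sigma_e2[1], truth.sigma_a12, truth.genetic_correlation,
                  truth.realized_fst],
    }).to_csv(out / "truth_parameters.csv", index=False)
    config.to_yaml(out / "config.yaml")
    return {"outdir": str(out), "n_animals": gm.n_animals, "n_snps": gm.n_snps}
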