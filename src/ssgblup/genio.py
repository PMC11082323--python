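"""Genotype, pedigree and phenotype IO plus quality control.

Dosage matrices are animals x SNPs arrays of float with values in {0, 1, 2}
and ``nan`` for missing.  Two on-disk dialects are supported: PLINK PED/MAP
(whitespace-delimited allele pairs, ``0`` = missing allele) and a plain
dosage CSV (header of SNP ids, one animal per row, explicit ``NA`` token).
The dosage CSV round-trips losslessly; PED cannot recover the coded-allele
orientation of a site where only one allele is observed (a limitation of the
format itself, not of this reader).

Quality control implements the standard chip-data rules for this kind of
study: per-animal call rate, chromosome set, per-SNP missing rate, minor
allele frequency, and a Hardy-Weinberg equilibrium test applied within each
breed separately (breeds have different allele frequencies, so a pooled test
would reject massively at structured loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_NAMES = frozenset({"305dMY", "MFY", "MPY", "SCS", "MFP", "MPP", "SCC"})

PED_COLUMNS = ["animal", "sire", "dam", "breed", "birth_year"]
PHENO_COLUMNS = ["animal", "breed", "trait", "value", "farm", "year_class", "season", "parity"]


@dataclass
class SnpMapError(Exception):
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.message


class GenotypeMatrix:
    """Animals x SNPs dosage matrix with breed labels.

    Parameters
    ----------
    animal_ids : sequence of str
        Row identifiers, unique.
    dosages : ndarray, shape (n_animals, n_snps)
        Values in {0, 1, 2}; ``nan`` marks a missing genotype.
    breeds : sequence of str
        Breed label per animal, aligned with ``animal_ids``.
    """

    def __init__(self, animal_ids, dosages, breeds):
        self.animal_ids = np.asarray(animal_ids, dtype=object)
        self.dosages = np.asarray(dosages, dtype=float)
        self.breeds = np.asarray(breeds, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if len(self.animal_ids) != self.dosages.shape[0]:
            raise ValueError("animal_ids length does not match dosage rows")
        if len(self.breeds) != len(self.animal_ids):
            raise ValueError("breeds length does not match animal_ids")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicated animal id in genotype matrix")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be coded 0/1/2 or missing")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def breed_of(self, animal_id) -> str:
        idx = np.flatnonzero(self.animal_ids == animal_id)
        if idx.size == 0:
            raise KeyError(animal_id)
        return self.breeds[idx[0]]

    def take_animals(self, row_idx) -> "GenotypeMatrix":
        row_idx = np.asarray(row_idx)
        return GenotypeMatrix(self.animal_ids[row_idx], self.dosages[row_idx], self.breeds[row_idx])

    def take_snps(self, col_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.animal_ids, self.dosages[:, np.asarray(col_idx)], self.breeds)

    def subset_ids(self, ids) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        row_idx = [pos[a] for a in ids]
        return self.take_animals(row_idx)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per animal."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Coded-allele frequency per SNP from non-missing entries."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.animal_ids.copy(), self.dosages.copy(), self.breeds.copy())


def make_snp_map(snp_ids, chromosomes, positions_bp, allele_coded=None, allele_other=None) -> pd.DataFrame:
    n = len(snp_ids)
    df = pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chromosome": np.asarray(chromosomes, dtype=int),
            "position_bp": np.asarray(positions_bp, dtype=int),
            "allele_coded": allele_coded if allele_coded is not None else ["B"] * n,
            "allele_other": allele_other if allele_other is not None else ["A"] * n,
        }
    )
    if (df["position_bp"] <= 0).any():
        raise SnpMapError("positions must be strictly positive (1-based bp)")
    return df


@dataclass
class QcReport:
    """Bookkeeping of removals per QC rule.

    ``animal_rules`` and ``snp_rules`` map rule name -> number removed by that
    rule (a SNP failing several rules is counted under each, so the sum of
    rule counts can exceed the total removed).
    """

    n_animals_in: int = 0
    n_animals_out: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0
    animal_rules: dict = field(default_factory=dict)
    snp_rules: dict = field(default_factory=dict)
    surviving_snp_ids: list = field(default_factory=list)
    intersection_size: int | None = None

    def to_tsv(self, path) -> None:
        rows = [("animals_in", self.n_animals_in), ("animals_out", self.n_animals_out),
                ("snps_in", self.n_snps_in), ("snps_out", self.n_snps_out)]
        rows += [(f"animal_rule:{k}", v) for k, v in self.animal_rules.items()]
        rows += [(f"snp_rule:{k}", v) for k, v in self.snp_rules.items()]
        if self.intersection_size is not None:
            rows.append(("intersection_size", self.intersection_size))
        pd.DataFrame(rows, columns=["item", "count"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

def write_plink_pedmap(gm: GenotypeMatrix, snp_map: pd.DataFrame, ped_path, map_path) -> None:
    """Write PED/MAP; breed is used as the family id, missing genotype is "0 0"."""
    with open(map_path, "w") as fh:
        for _, r in snp_map.iterrows():
            fh.write(f"{r.chromosome}\t{r.snp_id}\t0\t{r.position_bp}\n")
    coded = snp_map["allele_coded"].to_numpy()
    other = snp_map["allele_other"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(gm.animal_ids):
            fields = [str(gm.breeds[i]), str(animal), "0", "0", "0", "-9"]
            row = gm.dosages[i]
            for j in range(gm.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [other[j], other[j]]
                elif d == 1:
                    fields += [other[j], coded[j]]
                else:
                    fields += [coded[j], coded[j]]
            fh.write(" ".join(fields) + "\n")


def read_plink_pedmap(ped_path, map_path):
    """Read PED/MAP into (GenotypeMatrix, SnpMap).

    The coded (counted) allele of each SNP is the lexicographically greater of
    the two observed alleles; a site where only one allele is observed is
    coded with that allele as the *other* allele (dosage 0), since the text
    format cannot distinguish the orientations.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chromosome", "snp_id", "cm", "position_bp"])
    n_snps = len(mp)
    animal_ids, breeds, rows = [], [], []
    allele_pairs_per_snp = [set() for _ in range(n_snps)]
    raw = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            fid, iid = parts[0], parts[1]
            alleles = parts[6:]
            if len(alleles) != 2 * n_snps:
                raise ValueError(f"PED row for {iid} has {len(alleles)//2} genotypes, map has {n_snps}")
            if iid in animal_ids:
                raise ValueError(f"duplicated animal id {iid} in PED")
            animal_ids.append(iid)
            breeds.append(fid)
            raw.append(alleles)
            for j in range(n_snps):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                for al in (a, b):
                    if al != "0":
                        allele_pairs_per_snp[j].add(al)
    coded, other = [], []
    for j, obs in enumerate(allele_pairs_per_snp):
        if len(obs) > 2:
            raise ValueError(f"SNP {mp.snp_id.iloc[j]} has more than two alleles: {sorted(obs)}")
        srt = sorted(obs)
        if len(srt) == 2:
            other.append(srt[0])
            coded.append(srt[1])
        elif len(srt) == 1:
            other.append(srt[0])
            coded.append("B" if srt[0] != "B" else "C")
        else:
            other.append("A")
            coded.append("B")
    dosages = np.full((len(animal_ids), n_snps), np.nan)
    for i, alleles in enumerate(raw):
        for j in range(n_snps):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            if a == "0" or b == "0":
                continue
            dosages[i, j] = (a == coded[j]) + (b == coded[j])
    gm = GenotypeMatrix(animal_ids, dosages, breeds)
    snp_map = make_snp_map(mp["snp_id"], mp["chromosome"], mp["position_bp"], coded, other)
    return gm, snp_map


# ---------------------------------------------------------------------------
# Dosage CSV + table CSVs
# ---------------------------------------------------------------------------

def write_dosage_csv(gm: GenotypeMatrix, snp_map: pd.DataFrame, path) -> None:
    df = pd.DataFrame(gm.dosages, columns=list(snp_map["snp_id"]))
    df.insert(0, "breed", gm.breeds)
    df.insert(0, "animal", gm.animal_ids)
    df.to_csv(path, index=False, na_rep="NA")


def read_dosage_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, na_values=["NA"])
    ids = df["animal"].astype(str).to_numpy()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated animal id in dosage CSV")
    breeds = df["breed"].astype(str).to_numpy()
    dos = df.drop(columns=["animal", "breed"]).to_numpy(dtype=float)
    return GenotypeMatrix(ids, dos, breeds)


def write_pedigree_csv(ped: pd.DataFrame, path) -> None:
    ped[PED_COLUMNS].to_csv(path, index=False)


def read_pedigree_csv(path) -> pd.DataFrame:
    ped = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str, "breed": str})
    return ped


def write_phenotype_csv(pt: pd.DataFrame, path) -> None:
    pt[PHENO_COLUMNS].to_csv(path, index=False)


def read_phenotype_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"animal": str, "breed": str, "trait": str})


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_animals(gm: GenotypeMatrix, min_call_rate: float = 0.90):
    """Drop animals whose genotyping call rate is below ``min_call_rate``."""
    if gm.n_animals == 0:
        raise ValueError("empty genotype matrix")
    keep = gm.call_rate() >= min_call_rate
    if not keep.any():
        raise ValueError("all animals removed by call-rate filter")
    report = QcReport(n_animals_in=gm.n_animals, n_animals_out=int(keep.sum()),
                      animal_rules={"call_rate": int((~keep).sum())})
    return gm.take_animals(np.flatnonzero(keep)), report


def hwe_chisq_p(n_hom_other: int, n_het: int, n_hom_coded: int) -> float:
    """One-df chi-square HWE p-value from genotype counts."""
    n = n_hom_other + n_het + n_hom_coded
    if n == 0:
        return 1.0
    p = (2 * n_hom_coded + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_hom_other, n_het, n_hom_coded], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_p(n_hom_other: int, n_het: int, n_hom_coded: int) -> float:
    """Exact HWE test (sum of probabilities <= observed, conditioning on allele counts)."""
    n = n_hom_other + n_het + n_hom_coded
    n_rare = min(2 * n_hom_other + n_het, 2 * n_hom_coded + n_het)
    if n == 0 or n_rare == 0:
        return 1.0
    # log-probability of each possible heterozygote count with the same allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    def logp(h):
        r_hom = (n_rare - h) // 2
        c_hom = n - h - r_hom
        return (np.log(2) * h + gammaln(n + 1)
                - gammaln(h + 1) - gammaln(r_hom + 1) - gammaln(c_hom + 1)
                + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1))

    lps = np.array([logp(int(h)) for h in hets])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    obs_p = probs[np.where(hets == n_het)[0][0]]
    return float(probs[probs <= obs_p + 1e-12].sum())


def qc_snps(gm: GenotypeMatrix, snp_map: pd.DataFrame, max_missing: float = 0.10,
            min_maf: float = 0.01, hwe_alpha: float = 1e-6,
            chromosomes=frozenset(range(1, 31)), hwe_method: str = "chisq"):
    """Filter SNPs by chromosome set, missing rate, MAF, and within-breed HWE.

    A SNP survives iff its chromosome is in ``chromosomes`` AND its missing
    fraction is < ``max_missing`` AND its MAF is > ``min_maf`` AND the HWE
    p-value exceeds ``hwe_alpha`` in every breed present.
    """
    hwe_fn = {"chisq": hwe_chisq_p, "exact": hwe_exact_p}[hwe_method]
    n = gm.n_snps
    chrom_ok = snp_map["chromosome"].isin(chromosomes).to_numpy()
    miss_frac = np.isnan(gm.dosages).mean(axis=0)
    miss_ok = miss_frac < max_missing
    freq = gm.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    maf_ok = maf > min_maf

    hwe_ok = np.ones(n, dtype=bool)
    for breed in np.unique(gm.breeds):
        sub = gm.dosages[gm.breeds == breed]
        for j in range(n):
            col = sub[:, j]
            col = col[~np.isnan(col)]
            p = hwe_fn(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
            if p <= hwe_alpha:
                hwe_ok[j] = False

    keep = chrom_ok & miss_ok & maf_ok & hwe_ok
    report = QcReport(
        n_snps_in=n, n_snps_out=int(keep.sum()),
        snp_rules={
            "chromosome": int((~chrom_ok).sum()),
            "missing_rate": int((~miss_ok).sum()),
            "maf": int((~maf_ok).sum()),
            "hwe": int((~hwe_ok).sum()),
        },
        surviving_snp_ids=list(snp_map.loc[keep, "snp_id"]),
    )
    if not keep.any():
        import warnings

        warnings.warn("no SNPs survived QC", stacklevel=2)
    idx = np.flatnonzero(keep)
    return gm.take_snps(idx), snp_map.loc[keep].reset_index(drop=True), report


def intersect_snps(gm_a: GenotypeMatrix, map_a: pd.DataFrame,
                   gm_b: GenotypeMatrix, map_b: pd.DataFrame):
    """Restrict both panels to their common SNP ids, column-aligned (order of ``map_a``)."""
    common = [s for s in map_a["snp_id"] if s in set(map_b["snp_id"])]
    if not common:
        raise ValueError("empty SNP intersection between panels")
    pos_a = {s: i for i, s in enumerate(map_a["snp_id"])}
    pos_b = {s: i for i, s in enumerate(map_b["snp_id"])}
    ia = [pos_a[s] for s in common]
    ib = [pos_b[s] for s in common]
    out_map = map_a.iloc[ia].reset_index(drop=True)
    return gm_a.take_snps(ia), gm_b.take_snps(ib), out_map


def impute_mean(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by 2 x within-breed coded-allele frequency.

    The frequency is recomputed from the non-missing entries of each SNP
    within the animal's breed.  Raises if a SNP has no observed genotype in
    some breed (no frequency to impute from).
    """
    dos = gm.dosages.copy()
    for breed in np.unique(gm.breeds):
        rows = gm.breeds == breed
        sub = dos[rows]
        n_obs = (~np.isnan(sub)).sum(axis=0)
        if (n_obs == 0).any():
            j = int(np.flatnonzero(n_obs == 0)[0])
            raise ValueError(f"SNP column {j} entirely missing within breed {breed}")
        means = np.nanmean(sub, axis=0)
        sub = np.where(np.isnan(sub), means[None, :], sub)
        dos[rows] = sub
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.animal_ids = gm.animal_ids.copy()
    out.breeds = gm.breeds.copy()
    out.dosages = dos  # imputed values are continuous, bypass 0/1/2 validation
    return out


def screen_phenotypes(pt: pd.DataFrame, rules: dict):
    """Keep records whose value lies in the closed per-(breed, trait) interval.

    ``rules`` maps (breed, trait) -> (low, high).  Every (breed, trait)
    present in ``pt`` must have a rule; a rule naming an unknown trait is an
    error.
    """
    for (breed, trait) in rules:
        if trait not in TRAIT_NAMES:
            raise ValueError(f"unknown trait in screening rules: {trait}")
    present = set(zip(pt["breed"], pt["trait"]))
    missing = present - set(rules)
    if missing:
        raise ValueError(f"no screening rule for: {sorted(missing)}")
    keep = np.ones(len(pt), dtype=bool)
    counts = {}
    for (breed, trait), (lo, hi) in rules.items():
        mask = (pt["breed"] == breed) & (pt["trait"] == trait)
        bad = mask & ~pt["value"].between(lo, hi, inclusive="both")
        counts[(breed, trait)] = int(bad.sum())
        keep &= ~bad
    return pt.loc[keep].reset_index(drop=True), counts


def scc_to_scs(scc):
    """Somatic cell count (1,000 cells/mL) to somatic cell score: log2(SCC/100) + 3."""
    scc = np.asarray(scc, dtype=float)
    if (scc <= 0).any():
        raise ValueError("SCC must be positive")
    out = np.log2(scc / 100.0) + 3.0
    return float(out) if out.ndim == 0 else out


def derive_yield(milk_yield, percentage):
    """Component yield (kg) from 305-day milk yield and a fat/protein percentage."""
    return np.asarray(milk_yield, dtype=float) * np.asarray(percentage, dtype=float) / 100.0
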