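"""Population-structure diagnostics: LD decay, G-matrix PCA, kinship blocks.

LD is the composite (dosage-correlation) r^2 — the squared Pearson
correlation of 0/1/2 dosage vectors — which needs no phased haplotypes.
Missing dosages are pairwise-deleted.  PCA is an uncentered
eigendecomposition of G itself: G already encodes centering through the
allele frequencies used to build it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise-complete)."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance (monomorphic) input; filter upstream")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_decay(gm: GenotypeMatrix, snp_map: pd.DataFrame, max_distance_kb: float,
             bin_kb: float = 1.0, group=None) -> pd.DataFrame:
    """Mean r^2 of within-chromosome SNP pairs binned by bp distance.

    ``group`` optionally restricts to one breed label.  Bins are
    [k*bin_kb, (k+1)*bin_kb) kb; empty bins are reported with n_pairs = 0.
    Monomorphic SNPs (within the group) are skipped.
    """
    dos = gm.dosages if group is None else gm.dosages[gm.breeds == group]
    max_bp = max_distance_kb * 1000.0
    n_bins = int(np.ceil(max_distance_kb / bin_kb))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for _, grp in snp_map.groupby("chromosome"):
        cols = grp.index.to_numpy()
        pos = grp["position_bp"].to_numpy(dtype=float)
        order = np.argsort(pos)
        cols, pos = cols[order], pos[order]
        for i in range(len(cols)):
            j = i + 1
            while j < len(cols) and pos[j] - pos[i] <= max_bp:
                try:
                    r2 = ld_r2(dos[:, cols[i]], dos[:, cols[j]])
                except ValueError:
                    j += 1
                    continue
                k = min(int((pos[j] - pos[i]) / (bin_kb * 1000.0)), n_bins - 1)
                sums[k] += r2
                counts[k] += 1
                j += 1
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "distance_bin_kb": np.arange(n_bins) * bin_kb,
        "mean_r2": mean,
        "n_pairs": counts,
    })


@dataclass
class PcaResult:
    eigenvalues: np.ndarray   # descending
    eigenvectors: np.ndarray  # columns, aligned with eigenvalues, orthonormal
    pct_variance: np.ndarray  # eigenvalue / trace * 100

    def scores(self, k: int = 3) -> np.ndarray:
        """Per-animal coordinates on the first k components."""
        return self.eigenvectors[:, :k] * np.sqrt(np.maximum(self.eigenvalues[:k], 0.0))


def grm_pca(G: np.ndarray, sym_tol: float = 1e-8) -> PcaResult:
    """Eigendecomposition of a symmetric G, components ordered by eigenvalue."""
    G = np.asarray(G, dtype=float)
    if G.shape[0] != G.shape[1] or np.abs(G - G.T).max() > sym_tol * max(1.0, np.abs(G).max()):
        raise ValueError("G must be symmetric")
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    trace = vals.sum()
    pct = vals / trace * 100.0 if trace != 0 else np.zeros_like(vals)
    return PcaResult(eigenvalues=vals, eigenvectors=vecs, pct_variance=pct)


def kinship_blocks(G: np.ndarray, group_of) -> pd.DataFrame:
    """Mean G entry within and between group labels.

    ``group_of`` is a label per animal aligned with G's rows.  Within-group
    means exclude the diagonal; a singleton group's within-mean is NaN.
    Returns a square DataFrame indexed by group label.
    """
    labels = np.asarray(group_of)
    if labels.shape[0] != G.shape[0]:
        raise ValueError("group labels must align with G rows")
    groups = list(dict.fromkeys(labels))
    out = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for a in groups:
        ia = np.flatnonzero(labels == a)
        for b in groups:
            ib = np.flatnonzero(labels == b)
            block = G[np.ix_(ia, ib)]
            if a == b:
                if ia.size < 2:
                    continue
                mask = ~np.eye(ia.size, dtype=bool)
                out.loc[a, b] = float(block[mask].mean())
            else:
                out.loc[a, b] = float(block.mean())
    return out


def write_ld_decay_tsv(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, sep="\t", index=False)


def write_pca_tsv(result: PcaResult, animal_ids, path, k: int = 3) -> None:
    df = pd.DataFrame(result.scores(k), columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "animal", list(animal_ids))
    with open(path, "w") as fh:
        fh.write("# pct_variance: " + ", ".join(
            f"PC{i + 1}={result.pct_variance[i]:.3f}" for i in range(k)) + "\n")
        df.to_csv(fh, sep="\t", index=False)
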