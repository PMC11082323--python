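"""End-to-end orchestration: simulate -> qc -> structure -> evaluate -> validate.

Each stage reads the previous stage's artifacts from the output directory,
echoes the resolved configuration next to its outputs, and appends to a
structured run log.  All randomness flows from one global seed through named
substreams (sim, grouping, gibbs), so changing the scenario grid does not
perturb the simulated data.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import genio, popstruct, simdata
from .evalcv import DataBundle, run_validation_experiment
from .model import GibbsConfig, SingleStepGBLUP


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    seed: int = 1
    sim: simdata.SimConfig = dataclasses.field(default_factory=simdata.SimConfig)
    min_call_rate: float = 0.90
    max_missing: float = 0.10
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6
    chromosomes: tuple = tuple(range(1, 31))
    ld_max_distance_kb: float = 1000.0
    ld_bin_kb: float = 10.0
    blend_weight: float = 0.05
    chain_length: int = 5000
    burn_in: int = 1000
    thin: int = 5
    cv_step: int = 100
    cv_max_added: int | None = None
    cv_n_validation: int = 50
    cv_window_years: int = 4

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for k in ("ancestral_freq_range", "h2", "trait_means", "trait_sds", "breeds"):
            if k in sim_raw:
                sim_raw[k] = tuple(sim_raw[k])
        if "chromosomes" in raw:
            raw["chromosomes"] = tuple(raw["chromosomes"])
        cfg = cls(**raw, sim=simdata.SimConfig(**sim_raw))
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)

        def _clean(v):
            if isinstance(v, tuple):
                return [_clean(x) for x in v]
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            return v

        with open(path, "w") as fh:
            yaml.safe_dump(_clean(d), fh, sort_keys=False)

    def substream_seed(self, name: str) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=(hash(name) % 2**31,))
        return int(ss.generate_state(1)[0] % 2**31)


def _log(outdir: Path, stage: str, message: str) -> None:
    ts = datetime.datetime.now().isoformat(timespec="seconds")
    with open(outdir / "run.log", "a") as fh:
        fh.write(f"{ts}\t{stage}\t{message}\n")


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing artifact {path}; run `{produced_by}` first")
    return path


def cmd_simulate(config: RunConfig, outdir) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.substream_seed("sim"))
    info = simdata.write_dataset(out, sim)
    config.to_yaml(out / "run_config.yaml")
    _log(out, "simulate", f"version={__version__} seed={config.seed} "
         f"n_animals={info['n_animals']} n_snps={info['n_snps']}")
    return info


def cmd_qc(config: RunConfig, outdir) -> dict:
    out = Path(outdir)
    gm = genio.read_dosage_csv(_require(out / "genotypes.csv", "simulate"))
    snp_map = pd.read_csv(
        _require(out / "genotypes.map", "simulate"), sep=r"\s+", header=None,
        names=["chromosome", "snp_id", "cm", "position_bp"])
    snp_map = genio.make_snp_map(snp_map["snp_id"], snp_map["chromosome"],
                                 snp_map["position_bp"])
    # per-breed QC, then marker intersection, mirroring a two-chip workflow
    breeds = list(dict.fromkeys(gm.breeds))
    per_breed = []
    for breed in breeds:
        sub = gm.take_animals(np.flatnonzero(gm.breeds == breed))
        sub, rep_a = genio.qc_animals(sub, config.min_call_rate)
        sub, mp, rep_s = genio.qc_snps(sub, snp_map, config.max_missing,
                                       config.min_maf, config.hwe_alpha,
                                       set(config.chromosomes))
        per_breed.append((sub, mp, rep_a, rep_s))
    (gm_a, map_a, rep_a1, rep_s1), (gm_b, map_b, rep_a2, rep_s2) = per_breed
    gm_a, gm_b, common = genio.intersect_snps(gm_a, map_a, gm_b, map_b)
    merged = genio.GenotypeMatrix(
        np.concatenate([gm_a.animal_ids, gm_b.animal_ids]),
        np.vstack([gm_a.dosages, gm_b.dosages]),
        np.concatenate([gm_a.breeds, gm_b.breeds]))
    merged = genio.impute_mean(merged)
    genio.write_dosage_csv(merged, common, out / "genotypes_qc.csv")
    common.to_csv(out / "snp_map_qc.csv", index=False)
    for rep, name in ((rep_s1, breeds[0]), (rep_s2, breeds[1])):
        rep.intersection_size = len(common)
        rep.to_tsv(out / f"qc_report_{name}.tsv")
    config.to_yaml(out / "run_config.yaml")
    _log(out, "qc", f"snps_common={len(common)} animals={merged.n_animals}")
    return {"n_snps": len(common), "n_animals": merged.n_animals}


def cmd_structure(config: RunConfig, outdir) -> dict:
    from .relmat import vanraden_g

    out = Path(outdir)
    gm = genio.read_dosage_csv(_require(out / "genotypes_qc.csv", "qc"))
    snp_map = pd.read_csv(_require(out / "snp_map_qc.csv", "qc"))
    for breed in dict.fromkeys(gm.breeds):
        curve = popstruct.ld_decay(gm, snp_map, config.ld_max_distance_kb,
                                   config.ld_bin_kb, group=breed)
        popstruct.write_ld_decay_tsv(curve, out / f"ld_decay_{breed}.tsv")
    G = vanraden_g(gm.dosages)
    pca = popstruct.grm_pca(G)
    popstruct.write_pca_tsv(pca, gm.animal_ids, out / "pca.tsv")
    blocks = popstruct.kinship_blocks(G, gm.breeds)
    blocks.to_csv(out / "kinship_blocks.tsv", sep="\t")
    _log(out, "structure", f"pc1_pct={pca.pct_variance[0]:.3f}")
    return {"pct_variance": pca.pct_variance[:3].tolist()}


def _load_bundle(out: Path) -> DataBundle:
    gm = genio.read_dosage_csv(_require(out / "genotypes_qc.csv", "qc"))
    ped = genio.read_pedigree_csv(_require(out / "pedigree.csv", "simulate"))
    pt = genio.read_phenotype_csv(_require(out / "phenotypes.csv", "simulate"))
    breeds = list(dict.fromkeys(gm.breeds))
    trait_of = {b: f"trait_{b}" for b in breeds}
    return DataBundle(pedigree=ped, genotypes=gm, phenotypes=pt,
                      target_breed=breeds[0], other_breed=breeds[1],
                      trait_of_breed=trait_of)


def cmd_evaluate(config: RunConfig, outdir) -> dict:
    out = Path(outdir)
    data = _load_bundle(out)
    est = SingleStepGBLUP(traits=(data.trait_of_breed[data.target_breed],
                                  data.trait_of_breed[data.other_breed]),
                          blend_weight=config.blend_weight,
                          chain_length=config.chain_length, burn_in=config.burn_in,
                          thin=config.thin,
                          random_state=config.substream_seed("gibbs"))
    est.fit(data.phenotypes, pedigree=data.pedigree, genotypes=data.genotypes)
    est.gebv_.to_csv(out / "gebv.csv", index=False)
    est.posterior_.vc_chain.to_csv(out / "vc_chain.tsv", sep="\t", index=False)
    summary = pd.DataFrame({
        "parameter": ["sigma_a2_1", "sigma_a12", "sigma_a2_2", "sigma_e2_1",
                      "sigma_e2_2", "h2_1", "h2_2", "h2_se_1", "h2_se_2",
                      "genetic_correlation"],
        "value": [est.variance_components_.genetic[0, 0],
                  est.variance_components_.sigma_a12,
                  est.variance_components_.genetic[1, 1],
                  est.variance_components_.residual[0],
                  est.variance_components_.residual[1],
                  est.h2_[0], est.h2_[1], est.h2_se_[0], est.h2_se_[1],
                  est.genetic_correlation_],
    })
    summary.to_csv(out / "posterior_summary.csv", index=False)
    bad = {k: z for k, z in est.geweke_.items() if np.isfinite(z) and abs(z) > 3}
    if bad:
        _log(out, "evaluate", f"WARNING geweke |z|>3: {bad}")
    _log(out, "evaluate", f"h2={est.h2_.round(4).tolist()} retained={est.n_retained_}")
    return {"h2": est.h2_.tolist(), "n_retained": est.n_retained_}


def cmd_validate(config: RunConfig, outdir) -> dict:
    out = Path(outdir)
    data = _load_bundle(out)
    gibbs = GibbsConfig(chain_length=config.chain_length, burn_in=config.burn_in,
                        thin=config.thin, seed=config.substream_seed("gibbs"))
    report, results = run_validation_experiment(
        data, gibbs, step=config.cv_step, max_added=config.cv_max_added,
        n_validation=config.cv_n_validation, window_years=config.cv_window_years,
        grouping_seed=config.substream_seed("grouping"),
        blend_weight=config.blend_weight)
    report.to_csv(out / "validation_report.csv", index=False)
    vc_rows = []
    for res in results:
        size = len(res.reference_ids) + len(res.validation_ids)
        for run, vc, h2 in (("full", res.vc_full, res.h2_full),
                            ("reduced", res.vc_reduced, res.h2_reduced)):
            vc_rows.append((size, run, vc.genetic[0, 0], vc.genetic[1, 1],
                            vc.sigma_a12, vc.residual[0], vc.residual[1],
                            h2[0], h2[1]))
    pd.DataFrame(vc_rows, columns=["scenario_size", "run", "sigma_a2_1", "sigma_a2_2",
                                   "sigma_a12", "sigma_e2_1", "sigma_e2_2",
                                   "h2_1", "h2_2"]).to_csv(
        out / "validation_vc.csv", index=False)
    _log(out, "validate", f"scenarios={report['scenario_size'].nunique()}")
    return {"n_scenarios": int(report["scenario_size"].nunique())}
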