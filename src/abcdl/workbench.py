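"""Fixtures, observed-data ingestion and end-to-end pipelines.

``generate_toy_cohort`` simulates a synthetic genotype cohort under one of
the demographic models — two diploids per modern population and one per
archaic — and writes it to disk as a VCF with ancestral-allele (``AA``)
annotation, a block map BED and a ground-truth sidecar, emulating the shape
of the real genome panels without downloading anything.

Observed-data conventions: VCF coordinates are 1-based closed, the block
BED is 0-based half-open, and all internal arrays are 0-based.  Sites whose
ancestral allele matches neither REF nor ALT are unpolarizable and dropped
(counted in the read log).  The two-diploid design exists so the cohort can
be split in half: one half supplies the reference spectrum for SFS-like
noise injection during network training, the other is the ABC target; the
single archaic individuals are shared by both halves.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import abc_core, coalsim, dlsum, dstats
from .abc_core import AbcConfig, ModelPosterior, ParameterPosterior
from .coalsim import JointSFS, MutationRateSpec, RegionSpec
from .demography import (SAMPLED_POPULATIONS, ParameterVector, build_model,
                         sample_parameters, posterior_means, to_simulator_spec)
from .dlsum import NoiseSpec, TrainingSet
from .dstats import AlleleCountTable

__all__ = [
    "ToyCohort",
    "RunManifest",
    "generate_toy_cohort",
    "read_vcf_counts",
    "compute_observed_sfs",
    "simulate_training_set",
    "run_model_choice_pipeline",
    "run_estimation_pipeline",
]

MODERN_POPS = ("AFR", "EUR", "ASN", "AND", "IND", "PAP", "AUS")
ARCHAIC_POPS = ("NEAN", "DENI")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)

    @classmethod
    def start(cls, config: Mapping, seed: int) -> "RunManifest":
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
        return cls(config_hash=digest, seed=seed)

    def record(self, stage: str, **counters) -> None:
        self.stages.append({"stage": stage, "time": time.time(), **counters})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


# ---------------------------------------------------------------------------
# toy cohort generation
# ---------------------------------------------------------------------------

@dataclass
class ToyCohort:
    model_label: str
    params: dict
    populations: list[str]
    samples: list[str]                    # e.g. AFR_0, AFR_1, NEAN_0
    sample_pops: list[str]
    vcf_path: Path | None
    bed_path: Path | None
    truth_path: Path | None
    genotypes: np.ndarray                 # sites x samples, diploid derived count
    positions: np.ndarray                 # 1-based within contig
    contigs: np.ndarray                   # contig name per site
    blocks: np.ndarray                    # block id per site
    half_sfs: dict                        # {"noise": JointSFS, "target": JointSFS}
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.n_sites = len(self.positions)


def _cohort_samples() -> tuple[list[str], list[str]]:
    names, pops = [], []
    for p in SAMPLED_POPULATIONS:
        n = 2 if p in MODERN_POPS else 1
        for i in range(n):
            names.append(f"{p}_{i}")
            pops.append(p)
    return names, pops


def _vcf_header(samples: Sequence[str], contigs: Sequence[tuple[str, int]]) -> str:
    lines = ["##fileformat=VCFv4.2",
             "##source=abcdl-toy-cohort",
             '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines += [f"##contig=<ID={c},length={l}>" for c, l in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    return "\n".join(lines) + "\n"


def generate_toy_cohort(model_label: str,
                        params: Mapping[str, float] | str = "posterior-means",
                        scale: float = 0.001,
                        seed: int = 1,
                        out_dir: str | Path | None = None,
                        regions: Sequence[RegionSpec] | None = None,
                        mu_spec: MutationRateSpec | None = None) -> ToyCohort:
    """Simulate a genotype cohort and (optionally) write VCF + BED + truth.

    Two diploids per modern population, one per archaic.  Each region
    becomes its own VCF contig and jackknife block.  Deterministic for a
    fixed seed; site REF/ALT orientation is randomized so roughly half the
    sites need an ancestral-allele polarity flip on re-reading.
    """
    if isinstance(params, str):
        if params != "posterior-means":
            raise ValueError(f"unknown params preset {params!r}")
        pv: Mapping[str, float] = posterior_means(model_label)
    else:
        pv = params
    model = build_model(model_label)
    spec = to_simulator_spec(model, pv)
    regions = regions if regions is not None else coalsim.default_regions(scale=scale)
    mu_spec = mu_spec or MutationRateSpec()
    rng = np.random.default_rng(seed)
    mu = coalsim.sample_genome_mu(mu_spec, rng)
    seeds = rng.integers(1, 2**31 - 1, size=(len(regions), 2))
    samples, sample_pops = _cohort_samples()

    geno_chunks, pos_chunks, contig_chunks, block_chunks = [], [], [], []
    dem = coalsim.build_msprime_demography(spec)
    import msprime
    sample_sets = [msprime.SampleSet(2 if p in MODERN_POPS else 1, population=p)
                   for p in SAMPLED_POPULATIONS]
    for bi, (region, sp) in enumerate(zip(regions, seeds)):
        ts = msprime.sim_ancestry(
            samples=sample_sets, demography=dem,
            sequence_length=region.length,
            recombination_rate=region.recombination_rate, ploidy=2,
            random_seed=int(sp[0]))
        mts = msprime.sim_mutations(
            ts, rate=coalsim.region_mutation_rate(mu, region),
            model=msprime.BinaryMutationModel(), discrete_genome=False,
            random_seed=int(sp[1]))
        if mts.num_sites == 0:
            continue
        G = mts.genotype_matrix()  # sites x haplotypes
        # haplotypes are grouped per sample-set in order; collapse to diploids
        n_dip = G.shape[1] // 2
        dip = G[:, 0::2] + G[:, 1::2]
        positions = np.array([int(s.position) + 1 for s in mts.sites()])
        # resolve integer-position collisions deterministically
        for i in range(1, len(positions)):
            if positions[i] <= positions[i - 1]:
                positions[i] = positions[i - 1] + 1
        keep = positions <= region.length
        geno_chunks.append(dip[keep])
        pos_chunks.append(positions[keep])
        contig_chunks.append(np.full(keep.sum(), region.region_id, dtype=object))
        block_chunks.append(np.full(keep.sum(), bi, dtype=np.int64))
    if geno_chunks:
        genotypes = np.concatenate(geno_chunks)
        positions = np.concatenate(pos_chunks)
        contigs = np.concatenate(contig_chunks)
        blocks = np.concatenate(block_chunks)
    else:
        genotypes = np.zeros((0, len(samples)), dtype=np.int64)
        positions = np.zeros(0, dtype=np.int64)
        contigs = np.zeros(0, dtype=object)
        blocks = np.zeros(0, dtype=np.int64)

    half_sfs = {h: _half_sfs_from_genotypes(genotypes, sample_pops, h)
                for h in ("noise", "target")}

    vcf_path = bed_path = truth_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        flip = np.random.default_rng(seed + 7).random(len(positions)) < 0.5
        vcf_path = out_dir / f"cohort_{model_label}.vcf"
        with open(vcf_path, "w") as fh:
            fh.write(_vcf_header(samples, [(r.region_id, r.length) for r in regions]))
            for i in range(len(positions)):
                if flip[i]:  # REF is the derived allele; AA equals ALT
                    ref, alt, aa = "G", "A", "A"
                    gts = ["1/1" if g == 0 else ("0/1" if g == 1 else "0/0")
                           for g in genotypes[i]]
                else:
                    ref, alt, aa = "A", "G", "A"
                    gts = ["0/0" if g == 0 else ("0/1" if g == 1 else "1/1")
                           for g in genotypes[i]]
                fh.write(f"{contigs[i]}\t{positions[i]}\t.\t{ref}\t{alt}\t.\tPASS\t"
                         f"AA={aa}\tGT\t" + "\t".join(gts) + "\n")
        bed_path = out_dir / f"cohort_{model_label}.blocks.bed"
        with open(bed_path, "w") as fh:
            for bi, region in enumerate(regions):
                fh.write(f"{region.region_id}\t0\t{region.length}\t{bi}\n")
        truth_path = out_dir / f"cohort_{model_label}.truth.json"
        truth_path.write_text(json.dumps(
            {"model_label": model_label, "params": {k: float(v) for k, v in pv.items()},
             "seed": seed, "samples": samples, "sample_pops": sample_pops},
            indent=2))
    return ToyCohort(model_label, {k: float(v) for k, v in pv.items()},
                     list(SAMPLED_POPULATIONS), samples, sample_pops,
                     vcf_path, bed_path, truth_path, genotypes, positions,
                     contigs, blocks, half_sfs)


def _half_samples(sample_pops: Sequence[str], half: str) -> list[int]:
    """Column indices of the chosen half: modern diploid 0 ('noise') or 1
    ('target'); single archaic individuals join both halves."""
    if half not in ("noise", "target"):
        raise ValueError("half must be 'noise' or 'target'")
    pick = 0 if half == "noise" else 1
    idx, seen = [], {}
    for j, pop in enumerate(sample_pops):
        k = seen.get(pop, 0)
        seen[pop] = k + 1
        if k == pick or (pop in ARCHAIC_POPS and k == 0):
            idx.append(j)
    return idx


def _half_sfs_from_genotypes(genotypes: np.ndarray, sample_pops: Sequence[str],
                             half: str) -> JointSFS:
    idx = _half_samples(sample_pops, half)
    pops = [sample_pops[j] for j in idx]
    cells = np.zeros((3,) * len(idx), dtype=np.int64)
    if len(genotypes):
        counts = genotypes[:, idx]
        flat = np.ravel_multi_index(counts.T, cells.shape)
        np.add.at(cells.reshape(-1), flat, 1)
    return JointSFS(cells, pops)


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def _read_block_bed(path: str | Path) -> dict[str, list[tuple[int, int, int]]]:
    out: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, block = line.split()[:4]
            out.setdefault(chrom, []).append((int(start), int(end), int(block)))
    return out


def read_vcf_counts(vcf_path: str | Path,
                    sample_to_pop: Mapping[str, str],
                    block_map: str | Path | None = None,
                    n_blocks: int = 555) -> AlleleCountTable:
    """Read a VCF with AA annotation into an allele-count table.

    Genotypes are polarized against the AA tag: if AA equals ALT the
    derived allele is REF (polarity flip); sites whose AA matches neither
    allele, or with any all-missing population, are dropped and counted in
    ``table.read_log``.  Blocks come from the BED block map when given,
    otherwise from equal-span physical blocks.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    canon = list(SAMPLED_POPULATIONS)
    pops = sorted({sample_to_pop[s] for s in samples if s in sample_to_pop},
                  key=lambda p: (canon.index(p) if p in canon else len(canon), p))
    pop_cols = {p: [j for j, s in enumerate(samples) if sample_to_pop.get(s) == p]
                for p in pops}
    bed = _read_block_bed(block_map) if block_map is not None else None

    derived_rows, total_rows, blocks, positions, chroms = [], [], [], [], []
    log = {"sites_read": 0, "dropped_unpolarizable": 0, "dropped_missing": 0,
           "dropped_not_biallelic": 0, "dropped_no_block": 0}
    geno_rows = []
    for var in vcf:
        log["sites_read"] += 1
        if len(var.ALT) != 1:
            log["dropped_not_biallelic"] += 1
            continue
        aa = (var.INFO.get("AA") or "").upper().strip(".")
        if aa == var.REF.upper():
            flip = False
        elif aa == var.ALT[0].upper():
            flip = True
        else:
            log["dropped_unpolarizable"] += 1
            continue
        gt = np.asarray(var.genotype.array())[:, :2]  # alleles per sample
        missing = (gt < 0).any(axis=1)
        alt_count = np.where(missing, -1, (gt > 0).sum(axis=1))
        der = np.where(missing, -1, 2 - alt_count if flip else alt_count)
        d_row, t_row = [], []
        for p in pops:
            cols = pop_cols[p]
            ok = [c for c in cols if der[c] >= 0]
            d_row.append(int(der[ok].sum()) if ok else 0)
            t_row.append(2 * len(ok))
        if all(t == 0 for t in t_row):
            log["dropped_missing"] += 1
            continue
        if bed is not None:
            block = None
            for start, end, b in bed.get(var.CHROM, ()):
                if start <= var.POS - 1 < end:  # VCF 1-based vs BED half-open
                    block = b
                    break
            if block is None:
                log["dropped_no_block"] += 1
                continue
            blocks.append(block)
        derived_rows.append(d_row)
        total_rows.append(t_row)
        geno_rows.append(der)
        positions.append(var.POS)
        chroms.append(var.CHROM)
    n = len(derived_rows)
    derived = np.array(derived_rows, dtype=np.int64).reshape(n, len(pops))
    total = np.array(total_rows, dtype=np.int64).reshape(n, len(pops))
    if bed is not None:
        block_arr = np.array(blocks, dtype=np.int64)
    elif n:
        _, chrom_idx = np.unique(chroms, return_inverse=True)
        block_arr = dstats.assign_blocks(np.array(positions), chrom_idx, n_blocks)
    else:
        block_arr = np.zeros(0, dtype=np.int64)
    table = AlleleCountTable(pops, derived, total, block_arr)
    table.read_log = log
    table.sample_names = samples
    table.sample_pops = [sample_to_pop.get(s) for s in samples]
    table.sample_genotypes = (np.array(geno_rows, dtype=np.int64).reshape(n, len(samples))
                              if n else np.zeros((0, len(samples)), dtype=np.int64))
    return table


def compute_observed_sfs(counts: AlleleCountTable, half: str) -> JointSFS:
    """Joint SFS of one half of the observed cohort (one diploid per
    population), axis layout identical to the simulations."""
    geno = getattr(counts, "sample_genotypes", None)
    if geno is None:
        raise ValueError("table lacks per-sample genotypes; re-read the VCF")
    sample_pops = counts.sample_pops
    for pop in set(p for p in sample_pops if p in MODERN_POPS):
        if sample_pops.count(pop) < 2:
            raise ValueError(f"modern population {pop} has a single diploid; "
                             "cannot split halves")
    idx = _half_samples(sample_pops, half)
    ok = (geno[:, idx] >= 0).all(axis=1) if len(geno) else np.zeros(0, bool)
    return _half_sfs_from_genotypes(geno[ok], sample_pops, half)


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def simulate_training_set(model_label: str, n_sims: int,
                          regions: Sequence[RegionSpec],
                          mu_spec: MutationRateSpec,
                          rng: np.random.Generator,
                          fixed_params: Mapping[str, float] | None = None) -> TrainingSet:
    """Draw parameters from the prior and simulate one spectrum per draw."""
    model = build_model(model_label)
    records = []
    for _ in range(n_sims):
        pv = sample_parameters(model, rng)
        if fixed_params:
            pv.update(fixed_params)
        sfs = coalsim.simulate_joint_sfs(model, pv, regions, mu_spec, rng)
        records.append((dict(pv), sfs))
    ts = TrainingSet.from_records(records)
    ts.labels = np.array([model_label] * n_sims)
    return ts


def _resolve_observed(config: Mapping, manifest: RunManifest):
    """Return (target_sfs, noise_sfs) from a cohort directory or pseudo-
    observed generation config."""
    if "cohort_vcf" in config:
        truth = json.loads(Path(config["cohort_truth"]).read_text())
        table = read_vcf_counts(config["cohort_vcf"],
                                dict(zip(truth["samples"], truth["sample_pops"])),
                                block_map=config.get("cohort_bed"))
        manifest.record("read_observed", **table.read_log)
        return (compute_observed_sfs(table, "target"),
                compute_observed_sfs(table, "noise"))
    pseudo = config["pseudo_observed"]
    cohort = generate_toy_cohort(pseudo["model"],
                                 pseudo.get("params", "posterior-means"),
                                 seed=int(pseudo.get("seed", 1)),
                                 regions=_regions_from_config(config))
    manifest.record("pseudo_observed", model=pseudo["model"],
                    n_sites=cohort.n_sites)
    return cohort.half_sfs["target"], cohort.half_sfs["noise"]


def _regions_from_config(config: Mapping) -> list[RegionSpec]:
    return coalsim.default_regions(scale=float(config.get("region_scale", 0.001)))


def run_model_choice_pipeline(config: Mapping) -> tuple[ModelPosterior, RunManifest]:
    """simulate -> train (noise-injected) -> summarize -> reject -> mnlogistic."""
    seed = int(config.get("seed", 1))
    manifest = RunManifest.start(config, seed)
    rng = np.random.default_rng(seed)
    regions = _regions_from_config(config)
    mu_spec = MutationRateSpec()
    target_sfs, noise_sfs = _resolve_observed(config, manifest)

    labels = list(config.get("candidate_models", "AH"))
    n_sims = int(config.get("n_sims_per_model", 200))
    records_X, records_y = [], []
    for label in labels:
        ts = simulate_training_set(label, n_sims, regions, mu_spec, rng)
        records_X.append(ts.X)
        records_y.append(ts.labels)
        manifest.record("simulate", model=label, n_sims=n_sims)
    train = TrainingSet(list(SAMPLED_POPULATIONS), (3,) * 9,
                        np.vstack(records_X), labels=np.concatenate(records_y))
    noise = NoiseSpec(float(config.get("alpha_max", 0.2)), noise_sfs)
    net = dlsum.train_classifier_net(train, noise=noise,
                                     hyper=config.get("net_hyper"),
                                     rng_seed=seed)
    manifest.record("train", layers=len(net.layer_sizes))
    ss_sims = net.forward(train.X)
    ss_obs = dlsum.summarize(net, target_sfs)
    n_accept = int(config.get("n_accept", max(1, len(ss_sims) // 100)))
    choice = abc_core.ABCModelChoice(n_accept=n_accept).fit(ss_sims, train.labels)
    posterior = choice.posterior(ss_obs)
    manifest.record("model_choice", n_accept=n_accept, method=posterior.method,
                    **{f"P_{k}": v for k, v in posterior.probabilities.items()})
    return posterior, manifest


def run_estimation_pipeline(config: Mapping):
    """simulate -> train regressor -> summarize -> reject -> loclinear."""
    seed = int(config.get("seed", 1))
    manifest = RunManifest.start(config, seed)
    rng = np.random.default_rng(seed)
    regions = _regions_from_config(config)
    mu_spec = MutationRateSpec()
    target_sfs, noise_sfs = _resolve_observed(config, manifest)

    label = config.get("model", "H")
    n_sims = int(config.get("n_sims", 400))
    train = simulate_training_set(label, n_sims, regions, mu_spec, rng)
    manifest.record("simulate", model=label, n_sims=n_sims)
    targets = config.get("target_params")
    model = build_model(label)
    if targets is None:
        targets = [n for n, p in model.priors.items() if p.family != "fixed"]
    noise = NoiseSpec(float(config.get("alpha_max", 0.2)), noise_sfs)
    net = dlsum.train_regressor_net(train, noise=noise, target=targets,
                                    hyper=config.get("net_hyper"), rng_seed=seed)
    manifest.record("train", targets=len(targets))
    ss_sims = net.forward(train.X)
    ss_obs = dlsum.summarize(net, target_sfs)
    idx = [train.param_names.index(t) for t in targets]
    n_accept = int(config.get("n_accept", max(2, len(ss_sims) // 100)))
    est = abc_core.ABCParameterEstimator(n_accept=n_accept).fit(
        ss_sims, train.params[:, idx], param_names=targets)
    posterior = est.posterior(ss_obs)
    summary = abc_core.posterior_summary(posterior)
    manifest.record("estimate", n_accept=n_accept,
                    n_params=len(posterior.param_names))
    return posterior, summary, manifest
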