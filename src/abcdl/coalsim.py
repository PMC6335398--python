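"""Coalescent simulation of joint site-frequency spectra.

A demographic model plus one parameter draw is translated into an
:mod:`msprime` demography; genomes are simulated region by region (one
diploid per sampled population, so every SFS axis has three derived-allele
classes 0/1/2), mutations are laid down under an infinite-sites binary
model so every site is biallelic and polarized by the simulated ancestral
state, and the per-region spectra are summed.

The genome-wide mutation rate is drawn once per simulation from a normal
distribution (default 1.61e-8 +/- 0.13e-8 per bp per generation, truncated
at zero) and then scaled per region by the callable fraction
``mu_r = mu * L_c / L_r``, mirroring how masked sites thin the usable SNP
density of each region.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import msprime
import numpy as np

from .demography import DemographicModel, SimulatorSpec, to_simulator_spec

__all__ = [
    "RegionSpec",
    "MutationRateSpec",
    "JointSFS",
    "default_regions",
    "sample_genome_mu",
    "region_mutation_rate",
    "build_msprime_demography",
    "simulate_region",
    "sfs_from_ts",
    "simulate_joint_sfs",
    "marginalize_sfs",
    "write_sfs",
    "read_sfs",
]

#: full-scale region set: 9,643 regions totalling 651 Mb
FULL_N_REGIONS = 9_643
FULL_TOTAL_BP = 651_000_000
DEFAULT_RECOMBINATION = 1.0e-8


@dataclass(frozen=True)
class RegionSpec:
    """One genomic region: total length, callable length, recombination rate."""

    region_id: str
    length: int                      # L_r, bp
    callable_length: int             # L_c, bp after masking
    recombination_rate: float = DEFAULT_RECOMBINATION

    def __post_init__(self) -> None:
        if not 0 <= self.callable_length <= self.length:
            raise ValueError(f"region {self.region_id}: need 0 <= L_c <= L_r")


def default_regions(scale: float = 1.0, callable_fraction: float = 1.0,
                    recombination_rate: float = DEFAULT_RECOMBINATION) -> list[RegionSpec]:
    """Region set scaled down from the full 9,643-region / 651 Mb default.

    ``scale`` multiplies the region count (region length is kept at the
    full-scale average, ~67.5 kb), so total sequence is ``scale * 651 Mb``.
    """
    n = max(1, round(FULL_N_REGIONS * scale))
    length = round(FULL_TOTAL_BP / FULL_N_REGIONS)
    return [RegionSpec(f"region_{i}", length, round(length * callable_fraction),
                       recombination_rate) for i in range(n)]


@dataclass(frozen=True)
class MutationRateSpec:
    mean: float = 1.61e-8
    sd: float = 0.13e-8

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("need mean > 0 and sd >= 0")


def sample_genome_mu(spec: MutationRateSpec, rng: np.random.Generator) -> float:
    """One normal draw of the per-bp mutation rate, truncated at zero."""
    if spec.sd == 0:
        return spec.mean
    mu = rng.normal(spec.mean, spec.sd)
    while mu < 0:
        mu = rng.normal(spec.mean, spec.sd)
    return float(mu)


def region_mutation_rate(mu: float, region: RegionSpec) -> float:
    """Scale the genome-wide rate by the callable fraction of one region."""
    if region.length == 0:
        raise ValueError(f"region {region.region_id} has zero length")
    return mu * region.callable_length / region.length


# ---------------------------------------------------------------------------
# joint SFS container
# ---------------------------------------------------------------------------

class JointSFS:
    """Multidimensional joint site-frequency spectrum.

    One axis per sampled population; axis length is (2 * diploids + 1).
    Cell ``[i1, .., ik]`` counts sites where population j carries ``ij``
    derived alleles.  The all-ancestral and all-derived corner cells are
    recorded but excluded from summary vectors, so the included total is the
    number of polarized segregating sites.
    """

    def __init__(self, cells: np.ndarray, populations: Sequence[str]):
        cells = np.asarray(cells)
        if cells.ndim != len(populations):
            raise ValueError("one axis per population required")
        if np.any(cells < 0):
            raise ValueError("SFS cells must be nonnegative")
        self.cells = cells
        self.populations = list(populations)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.cells.shape

    def same_layout(self, other: "JointSFS") -> bool:
        return self.populations == other.populations and self.shape == other.shape

    def _corner_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask[(0,) * self.cells.ndim] = True
        mask[tuple(s - 1 for s in self.shape)] = True
        return mask

    def included_sum(self) -> float:
        """Total count over non-corner cells (polarized segregating sites)."""
        return float(self.cells.sum() - self.cells[(0,) * self.cells.ndim]
                     - self.cells[tuple(s - 1 for s in self.shape)])

    def to_vector(self) -> np.ndarray:
        """Flatten to the summary-statistic vector (corner cells dropped)."""
        flat = self.cells.reshape(-1)
        keep = ~self._corner_mask().reshape(-1)
        return np.asarray(flat[keep], dtype=float)

    def copy(self) -> "JointSFS":
        return JointSFS(self.cells.copy(), list(self.populations))

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, JointSFS) and self.same_layout(other)
                and np.array_equal(self.cells, other.cells))


def marginalize_sfs(sfs: JointSFS, populations: Sequence[str]) -> JointSFS:
    """Sum over the axes of all populations not in ``populations``.

    The result's axes follow the requested order; the total (all-cell) count
    is conserved.
    """
    if not populations:
        raise ValueError("need a nonempty population subset")
    unknown = set(populations) - set(sfs.populations)
    if unknown:
        raise ValueError(f"unknown populations {sorted(unknown)}")
    keep_idx = [sfs.populations.index(p) for p in populations]
    drop = tuple(i for i in range(sfs.cells.ndim) if i not in keep_idx)
    cells = sfs.cells.sum(axis=drop) if drop else sfs.cells
    # axes currently ordered by original position of kept pops; reorder
    current = [p for p in sfs.populations if p in set(populations)]
    perm = [current.index(p) for p in populations]
    return JointSFS(np.transpose(cells, perm), list(populations))


# ---------------------------------------------------------------------------
# msprime adapter
# ---------------------------------------------------------------------------

def build_msprime_demography(spec: SimulatorSpec) -> msprime.Demography:
    """Translate a simulator-neutral spec into an msprime demography."""
    dem = msprime.Demography()
    for name, size, _stime, _sampled in spec.populations:
        dem.add_population(name=name, initial_size=size)
    for ev in spec.events:
        if ev.op == "migration":
            a, b, rate = ev.args
            dem.set_symmetric_migration_rate([a, b], rate)
        elif ev.op == "split":
            derived, ancestral = ev.args
            derived = list(derived)
            if len(derived) == 1:
                # side branch joining an already-live lineage
                dem.add_mass_migration(time=ev.time, source=derived[0],
                                       dest=ancestral, proportion=1.0)
            else:
                dem.add_population_split(time=ev.time, derived=derived,
                                         ancestral=ancestral)
        elif ev.op == "pulse":
            recipient, donor, frac = ev.args
            # backwards in time: recipient lineages jump into the donor
            dem.add_mass_migration(time=ev.time, source=recipient, dest=donor,
                                   proportion=frac)
        elif ev.op == "admixed_origin":
            pop, sources, props = ev.args
            nonzero = [(s, p) for s, p in zip(sources, props) if p > 0]
            if len(nonzero) == 1:
                dem.add_mass_migration(time=ev.time, source=pop,
                                       dest=nonzero[0][0], proportion=1.0)
            else:
                dem.add_admixture(time=ev.time, derived=pop,
                                  ancestral=[s for s, _ in nonzero],
                                  proportions=[p for _, p in nonzero])
        else:
            raise ValueError(f"unknown op {ev.op!r}")
    dem.sort_events()
    return dem


def _sample_sets(spec: SimulatorSpec) -> list[str]:
    return [name for name, _s, _t, sampled in spec.populations if sampled]


def simulate_region(spec: SimulatorSpec, region: RegionSpec, mu_region: float,
                    seed_pair: tuple[int, int], diploids_per_pop: int = 1):
    """Simulate one region; returns a mutated tree sequence.

    Sites are biallelic (binary infinite-sites mutations) with ancestral
    state 0, so derived-allele polarization is exact.
    """
    dem = build_msprime_demography(spec)
    sample_times = {name: t for name, _s, t, sampled in spec.populations if sampled}
    samples = [msprime.SampleSet(diploids_per_pop, population=p, time=sample_times[p])
               for p in _sample_sets(spec)]
    ts = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=region.length,
        recombination_rate=region.recombination_rate, ploidy=2,
        random_seed=seed_pair[0])
    return msprime.sim_mutations(
        ts, rate=mu_region, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=seed_pair[1])


def sfs_from_ts(ts, populations: Sequence[str],
                sample_sets: Sequence[np.ndarray] | None = None) -> np.ndarray:
    """Accumulate the joint SFS array of one tree sequence.

    Axis j has length ``len(sample_sets[j]) + 1``; by default each
    population's full sample set is used.
    """
    if sample_sets is None:
        pop_ids = {p.metadata["name"]: p.id for p in ts.populations()}
        sample_sets = [ts.samples(population=pop_ids[p]) for p in populations]
    shape = tuple(len(s) + 1 for s in sample_sets)
    out = np.zeros(shape, dtype=np.int64)
    if ts.num_sites == 0:
        return out
    G = ts.genotype_matrix()  # sites x samples, 0/1
    counts = np.stack([G[:, s].sum(axis=1) for s in sample_sets], axis=1)
    flat = np.ravel_multi_index(counts.T, shape)
    np.add.at(out.reshape(-1), flat, 1)
    return out


def _region_seeds(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(1, 2**31 - 1, size=(n, 2))


def simulate_joint_sfs(model: DemographicModel | SimulatorSpec,
                       params: Mapping[str, float] | None,
                       regions: Sequence[RegionSpec],
                       mu_spec: MutationRateSpec,
                       rng: np.random.Generator,
                       mu_per_region: bool = False,
                       diploids_per_pop: int = 1) -> JointSFS:
    """Simulate all regions and sum their joint spectra.

    One mutation-rate draw is shared by all regions before per-region
    scaling; pass ``mu_per_region=True`` to redraw per region instead.
    Deterministic for a fixed generator state.
    """
    if not regions:
        raise ValueError("empty region list")
    spec = model if isinstance(model, SimulatorSpec) else to_simulator_spec(model, params)
    pops = _sample_sets(spec)
    cells = np.zeros((2 * diploids_per_pop + 1,) * len(pops), dtype=np.int64)
    mu = sample_genome_mu(mu_spec, rng)
    seeds = _region_seeds(rng, len(regions))
    for region, seed_pair in zip(regions, seeds):
        if mu_per_region:
            mu = sample_genome_mu(mu_spec, rng)
        ts = simulate_region(spec, region, region_mutation_rate(mu, region),
                             (int(seed_pair[0]), int(seed_pair[1])),
                             diploids_per_pop=diploids_per_pop)
        cells += sfs_from_ts(ts, pops)
    return JointSFS(cells, pops)


# ---------------------------------------------------------------------------
# multiSFS-style text I/O
# ---------------------------------------------------------------------------

def write_sfs(sfs: JointSFS, path_or_buf) -> None:
    """Write as flat multiSFS text: header, population order, axis sizes,
    then all cells in C order on one tab-separated line."""
    own = isinstance(path_or_buf, (str, bytes))
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write("# abcdl multiSFS 1\n")
        fh.write("\t".join(sfs.populations) + "\n")
        fh.write("\t".join(str(s) for s in sfs.shape) + "\n")
        flat = sfs.cells.reshape(-1)
        if np.issubdtype(sfs.cells.dtype, np.integer):
            fh.write("\t".join(str(int(v)) for v in flat) + "\n")
        else:
            fh.write("\t".join(repr(float(v)) for v in flat) + "\n")
    finally:
        if own:
            fh.close()


def read_sfs(path_or_buf) -> JointSFS:
    own = isinstance(path_or_buf, (str, bytes))
    fh = open(path_or_buf) if own else path_or_buf
    try:
        header = fh.readline()
        if not header.startswith("# abcdl multiSFS"):
            raise ValueError("not an abcdl multiSFS file")
        pops = fh.readline().rstrip("\n").split("\t")
        shape = tuple(int(x) for x in fh.readline().split())
        fields = fh.readline().split()
        if all("." not in f and "e" not in f and "E" not in f for f in fields):
            cells = np.array([int(f) for f in fields], dtype=np.int64)
        else:
            cells = np.array([float(f) for f in fields], dtype=float)
        return JointSFS(cells.reshape(shape), pops)
    finally:
        if own:
            fh.close()
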