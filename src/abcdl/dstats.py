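"""Patterson's D, f4 and F4-ratio statistics with weighted block jackknife,
and simulation-based fitting of introgression fractions to observed D values.

Statistics are frequency-based: with one diploid per population, derived
allele frequencies take values {0, 1/2, 1}.  The ``Ancestral`` pseudo-
population (derived frequency 0 at every site) can occupy the fourth slot of
a quadruple, matching the use of inferred ancestral alleles as outgroup.

For a quadruple (W, X, Y, Z) with per-site derived frequencies w, x, y, z:

    f4   = mean over sites of (w - x)(y - z)
    D    = sum (w - x)(y - z) / sum (w + x - 2wx)(y + z - 2yz)

so D(AFR, ASN, NEAN, Ancestral) is negative when East Asians share an excess
of derived alleles with the Neanderthal.  Standard errors come from a
delete-one-block jackknife over contiguous genome blocks, weighted by block
size (Busing-style), robust to linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from . import coalsim
from .coalsim import JointSFS, MutationRateSpec, RegionSpec
from .demography import ParameterVector, build_model, posterior_means, to_simulator_spec

__all__ = [
    "AlleleCountTable",
    "DStatResult",
    "F4RatioResult",
    "STANDARD_QUADS",
    "f4",
    "patterson_d",
    "weighted_block_jackknife",
    "f4_ratio",
    "d_from_sfs",
    "simulate_d_vector",
    "fit_introgression",
    "assign_blocks",
]

ANCESTRAL = "Ancestral"
#: pooled-population aliases usable in quadruples
POP_ALIASES: dict[str, tuple[str, ...]] = {"PAC": ("PAP", "AUS")}

#: the five observed quadruples used when fitting introgression fractions
STANDARD_QUADS = (
    ("EUR", "AFR", "NEAN", ANCESTRAL),
    ("ASN", "AFR", "NEAN", ANCESTRAL),
    ("PAC", "AFR", "DENI", ANCESTRAL),
    ("ASN", "EUR", "NEAN", ANCESTRAL),
    ("ASN", "EUR", "DENI", ANCESTRAL),
)


class AlleleCountTable:
    """Per-site, per-population derived-allele counts with block labels.

    ``derived`` and ``total`` are (sites x populations) integer arrays; a
    population with ``total == 0`` at a site is missing there.  ``blocks``
    assigns each site to a contiguous genome block for the jackknife.
    """

    def __init__(self, populations: Sequence[str], derived: np.ndarray,
                 total: np.ndarray, blocks: np.ndarray,
                 polarized: bool = True):
        derived = np.asarray(derived, dtype=np.int64)
        total = np.asarray(total, dtype=np.int64)
        blocks = np.asarray(blocks, dtype=np.int64)
        if derived.shape != total.shape or derived.shape[0] != blocks.shape[0]:
            raise ValueError("shape mismatch between derived/total/blocks")
        if derived.shape[1] != len(populations):
            raise ValueError("one column per population required")
        if np.any(derived < 0) or np.any(derived > total):
            raise ValueError("need 0 <= derived <= total")
        self.populations = list(populations)
        self.derived = derived
        self.total = total
        self.blocks = blocks
        self.polarized = polarized

    @property
    def n_sites(self) -> int:
        return self.derived.shape[0]

    def n_blocks(self) -> int:
        return len(np.unique(self.blocks))

    def _column(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """(derived, total) for a population, alias, or the ancestral slot."""
        if pop == ANCESTRAL:
            n = self.n_sites
            return np.zeros(n, dtype=np.int64), np.ones(n, dtype=np.int64)
        names = POP_ALIASES.get(pop, (pop,))
        missing = [n for n in names if n not in self.populations]
        if missing:
            raise KeyError(f"population(s) {missing} not in table")
        idx = [self.populations.index(n) for n in names]
        return self.derived[:, idx].sum(axis=1), self.total[:, idx].sum(axis=1)


def assign_blocks(positions: np.ndarray, chrom_ids: np.ndarray | None = None,
                  n_blocks: int = 555) -> np.ndarray:
    """Equal-span physical blocks (default 555) over the site positions.

    With ``chrom_ids`` given, the span is partitioned per chromosome in
    proportion to its length so block boundaries never cross chromosomes.
    """
    positions = np.asarray(positions, dtype=float)
    if chrom_ids is None:
        chrom_ids = np.zeros(len(positions), dtype=np.int64)
    chrom_ids = np.asarray(chrom_ids)
    uniq, inv = np.unique(chrom_ids, return_inverse=True)
    spans = np.array([positions[inv == i].max() - positions[inv == i].min() + 1.0
                      for i in range(len(uniq))])
    per_chrom = np.maximum(1, np.round(n_blocks * spans / spans.sum()).astype(int))
    out = np.zeros(len(positions), dtype=np.int64)
    offset = 0
    for i in range(len(uniq)):
        sel = inv == i
        p = positions[sel]
        lo, hi = p.min(), p.max() + 1.0
        b = np.minimum((per_chrom[i] * (p - lo) / (hi - lo)).astype(int),
                       per_chrom[i] - 1)
        out[sel] = b + offset
        offset += per_chrom[i]
    return out


@dataclass(frozen=True)
class DStatResult:
    quadruple: tuple[str, str, str, str]
    D: float
    SE: float
    Z: float
    n_blocks: int
    n_sites: int


@dataclass(frozen=True)
class F4RatioResult:
    numerator: tuple[str, str, str, str]
    denominator: tuple[str, str, str, str]
    ratio: float
    SE: float
    n_blocks: int


# ---------------------------------------------------------------------------
# block sums
# ---------------------------------------------------------------------------

def _site_terms(counts: AlleleCountTable, quad: Sequence[str]):
    """Per-site numerator/denominator terms and the valid-site mask."""
    freqs = []
    valid = np.ones(counts.n_sites, dtype=bool)
    for pop in quad:
        der, tot = counts._column(pop)
        valid &= tot > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs.append(np.where(tot > 0, der / np.maximum(tot, 1), np.nan))
    w, x, y, z = freqs
    num = (w - x) * (y - z)
    den = (w + x - 2 * w * x) * (y + z - 2 * y * z)
    return num, den, valid


def _block_sums(values: np.ndarray, blocks: np.ndarray, valid: np.ndarray,
                block_ids: np.ndarray) -> np.ndarray:
    out = np.zeros(len(block_ids))
    sums = {b: s for b, s in zip(*_groupsum(blocks[valid], values[valid]))}
    for i, b in enumerate(block_ids):
        out[i] = sums.get(b, 0.0)
    return out


def _groupsum(keys: np.ndarray, values: np.ndarray):
    uniq, inv = np.unique(keys, return_inverse=True)
    return uniq, np.bincount(inv, weights=values)


def f4(counts: AlleleCountTable, quad: Sequence[str]):
    """Per-block f4 numerator sums and site counts.

    Returns ``(block_ids, block_num, block_n)``; the genome-wide f4 is
    ``block_num.sum() / block_n.sum()``.  Sites missing in any of the four
    populations are dropped listwise.
    """
    quad = tuple(quad)
    if len(quad) != 4:
        raise ValueError("quadruple must have four entries")
    num, _den, valid = _site_terms(counts, quad)
    block_ids = np.unique(counts.blocks)
    bnum = _block_sums(num, counts.blocks, valid, block_ids)
    bn = _block_sums(np.ones(counts.n_sites), counts.blocks, valid, block_ids)
    return block_ids, bnum, bn


def weighted_block_jackknife(estimate: float, loo_estimates: np.ndarray,
                             block_weights: np.ndarray) -> tuple[float, float]:
    """Busing-style weighted delete-one-block jackknife.

    Parameters are the full-data ``estimate``, the delete-one-block
    estimates and the block weights (site counts).  Returns the
    bias-corrected estimate and its standard error.  With equal weights this
    reduces to the textbook unweighted delete-one jackknife.
    """
    loo = np.asarray(loo_estimates, dtype=float)
    m = np.asarray(block_weights, dtype=float)
    g = len(loo)
    if g < 2:
        raise ValueError("need at least 2 blocks for a jackknife")
    if np.any(m <= 0):
        raise ValueError("block weights must be positive")
    n = m.sum()
    est_j = g * estimate - np.sum((1.0 - m / n) * loo)
    h = n / m
    tau = h * estimate - (h - 1.0) * loo  # weighted pseudovalues
    var = np.sum((tau - est_j) ** 2 / (h - 1.0)) / g
    return float(est_j), float(np.sqrt(max(var, 0.0)))


def patterson_d(counts: AlleleCountTable, quad: Sequence[str]) -> DStatResult:
    """Patterson's D with weighted block-jackknife standard error."""
    quad = tuple(quad)
    num, den, valid = _site_terms(counts, quad)
    if valid.sum() == 0:
        raise ValueError("no sites with complete data for this quadruple")
    block_ids = np.unique(counts.blocks)
    bnum = _block_sums(num, counts.blocks, valid, block_ids)
    bden = _block_sums(den, counts.blocks, valid, block_ids)
    bn = _block_sums(np.ones(counts.n_sites), counts.blocks, valid, block_ids)
    informative = bn > 0
    bnum, bden, bn = bnum[informative], bden[informative], bn[informative]
    tot_num, tot_den = bnum.sum(), bden.sum()
    if tot_den == 0:
        raise ValueError("zero D denominator: no informative sites")
    d_hat = tot_num / tot_den
    if len(bnum) >= 2 and np.all(np.abs(tot_den - bden) > 0):
        loo = (tot_num - bnum) / (tot_den - bden)
        _, se = weighted_block_jackknife(d_hat, loo, bn)
    else:
        se = 0.0
    z = d_hat / se if se > 0 else np.inf * np.sign(d_hat) if d_hat else 0.0
    return DStatResult(quad, float(d_hat), float(se), float(z),
                       n_blocks=len(bnum), n_sites=int(bn.sum()))


def f4_ratio(counts: AlleleCountTable, num_quad: Sequence[str],
             den_quad: Sequence[str], tol: float = 1e-12) -> F4RatioResult:
    """Ratio of two f4 statistics, SE by jackknifing the ratio per block."""
    ids1, n1, c1 = f4(counts, num_quad)
    ids2, n2, c2 = f4(counts, den_quad)
    if not np.array_equal(ids1, ids2):
        raise ValueError("block structures differ between quadruples")
    keep = (c1 > 0) | (c2 > 0)
    n1, c1, n2, c2 = n1[keep], c1[keep], n2[keep], c2[keep]
    f4n = n1.sum() / c1.sum()
    f4d = n2.sum() / c2.sum()
    if abs(f4d) < tol:
        raise ValueError("denominator f4 indistinguishable from zero")
    ratio = f4n / f4d
    if len(n1) >= 2:
        loo_n = (n1.sum() - n1) / np.maximum(c1.sum() - c1, 1)
        loo_d = (n2.sum() - n2) / np.maximum(c2.sum() - c2, 1)
        if np.any(np.abs(loo_d) < tol):
            raise ValueError("denominator f4 vanishes in a jackknife block")
        _, se = weighted_block_jackknife(ratio, loo_n / loo_d, c1 + c2)
    else:
        se = 0.0
    return F4RatioResult(tuple(num_quad), tuple(den_quad), float(ratio),
                         float(se), n_blocks=len(n1))


# ---------------------------------------------------------------------------
# D from a joint SFS (used for simulation-based fitting)
# ---------------------------------------------------------------------------

def _quad_pop_names(quad: Sequence[str]) -> list[str]:
    names: list[str] = []
    for pop in quad:
        if pop == ANCESTRAL:
            continue
        names.extend(POP_ALIASES.get(pop, (pop,)))
    return names


def d_from_sfs(sfs: JointSFS, quad: Sequence[str]) -> float:
    """Patterson's D computed exactly from joint-SFS cell counts.

    Works on the marginal spectrum of the (up to four) populations in the
    quadruple; pooled aliases (e.g. PAC = PAP + AUS) average their derived
    counts; the ``Ancestral`` slot contributes frequency 0.
    """
    sums = d_sums_from_sfs(sfs, quad)
    if sums[1] == 0:
        raise ValueError("zero D denominator in SFS")
    return float(sums[0] / sums[1])


def d_sums_from_sfs(sfs: JointSFS, quad: Sequence[str]) -> tuple[float, float]:
    """(numerator sum, denominator sum) of D over all cells of the SFS."""
    pops = _quad_pop_names(quad)
    marg = coalsim.marginalize_sfs(sfs, pops)
    grids = np.meshgrid(*[np.arange(s) for s in marg.shape], indexing="ij")
    freqs = []
    for pop in quad:
        if pop == ANCESTRAL:
            freqs.append(np.zeros(marg.shape))
            continue
        names = POP_ALIASES.get(pop, (pop,))
        idx = [pops.index(n) for n in names]
        der = sum(grids[i] for i in idx)
        tot = sum(marg.shape[i] - 1 for i in idx)
        freqs.append(der / tot)
    w, x, y, z = freqs
    num = (w - x) * (y - z)
    den = (w + x - 2 * w * x) * (y + z - 2 * y * z)
    cells = marg.cells
    return float((cells * num).sum()), float((cells * den).sum())


# ---------------------------------------------------------------------------
# introgression-fraction fitting
# ---------------------------------------------------------------------------

def simulate_d_vector(model_label: str, params: Mapping[str, float],
                      quads: Sequence[Sequence[str]],
                      regions: Sequence[RegionSpec], n_reps: int,
                      seed: int, mu_spec: MutationRateSpec | None = None) -> np.ndarray:
    """Mean simulated D for each quadruple, pooling sites over replicates."""
    mu_spec = mu_spec or MutationRateSpec()
    model = build_model(model_label)
    spec = to_simulator_spec(model, params)
    num = np.zeros(len(quads))
    den = np.zeros(len(quads))
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        sfs = coalsim.simulate_joint_sfs(spec, None, regions, mu_spec, rng)
        for qi, quad in enumerate(quads):
            a, b = d_sums_from_sfs(sfs, quad)
            num[qi] += a
            den[qi] += b
    if np.any(den == 0):
        raise ValueError("zero D denominator in pooled simulations")
    return num / den


@dataclass
class IntrogressionFit:
    free_params: tuple[str, ...]
    estimate: np.ndarray
    objective: float
    success: bool
    message: str
    trace: list[tuple[np.ndarray, float]]


def fit_introgression(observed: Mapping[tuple, float] | Sequence[DStatResult],
                      free_params: Sequence[str],
                      model_label: str = "A",
                      fixed_params: Mapping[str, float] | None = None,
                      regions: Sequence[RegionSpec] | None = None,
                      n_reps: int = 200,
                      seed: int = 1,
                      bounds: Sequence[tuple[float, float]] | None = None,
                      quads: Sequence[Sequence[str]] = STANDARD_QUADS) -> IntrogressionFit:
    """Fit introgression fraction(s) to observed D values by simulation.

    Minimizes the squared distance between the observed D vector and the
    simulation-mean D vector as a function of the free fraction parameter(s),
    holding every other parameter fixed (default: the posterior-mean point
    estimates of the base model).  Uses bounded scalar minimization for one
    free parameter and bounded L-BFGS-B for two or more.  Simulations reuse
    the same seed sequence at every evaluation (common random numbers) so
    the objective is a deterministic function of the fractions.
    """
    if isinstance(observed, Mapping):
        obs = np.array([observed[tuple(q)] for q in quads])
    else:
        by_quad = {r.quadruple: r.D for r in observed}
        obs = np.array([by_quad[tuple(q)] for q in quads])
    free_params = tuple(free_params)
    base = dict(posterior_means(model_label))
    base.update(fixed_params or {})
    regions = regions if regions is not None else coalsim.default_regions(scale=0.0005)
    if bounds is None:
        bounds = [(0.0, 0.2)] * len(free_params)
    trace: list[tuple[np.ndarray, float]] = []

    def objective(x: np.ndarray) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        params = dict(base)
        for name, v in zip(free_params, x):
            params[name] = float(np.clip(v, bounds[free_params.index(name)][0],
                                         bounds[free_params.index(name)][1]))
        sim_d = simulate_d_vector(model_label, params, quads, regions, n_reps, seed)
        val = float(np.sum((obs - sim_d) ** 2))
        trace.append((x.copy(), val))
        return val

    if len(free_params) == 1:
        res = optimize.minimize_scalar(lambda v: objective(np.array([v])),
                                       bounds=bounds[0], method="bounded",
                                       options={"xatol": 1e-3})
        est = np.array([res.x])
        ok, msg, fun = res.success, str(res.message), res.fun
    else:
        x0 = np.array([(lo + hi) / 2 for lo, hi in bounds])
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                                options={"eps": 5e-3, "maxiter": 50})
        est, ok, msg, fun = res.x, res.success, str(res.message), res.fun
    if not ok:
        msg = f"optimizer did not converge: {msg}; trace has {len(trace)} evaluations"
    return IntrogressionFit(free_params, est, float(fun), bool(ok), msg, trace)
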