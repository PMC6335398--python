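# Methods

`abcdl` implements likelihood-free inference of archaic-introgression
histories for Eurasian and Oceanian human populations: coalescent simulation
of competing demographic models, compression of the multidimensional joint
site-frequency spectrum (SFS) into low-dimensional summaries with a
feedforward network, and approximate Bayesian computation (ABC) for model
choice and parameter estimation, together with the D / F4-ratio machinery
used to motivate and validate the models.

## The demographic models

Eight models (`A`–`H`, `abcdl.demography`) share a modern-human backbone:
an African / Out-of-Africa (OOA) split (`t_eurasia_a`), a European /
Asia-Pacific split (`t_e_asia_pacific`), an Asian clade of East Asians,
Andamanese and Indians (`t_ea_an_i`, modelled as a trifurcation) joining a
Papuan–Australian clade (`t_pap_aus`) at `t_asia_pacific`; Neanderthal and
Denisovan branches splitting at `t_n_d` from a common archaic ancestor that
leaves the modern-human lineage at `t_hominin`; and a deep *Homo
erectus*-like ghost Xd branching at `t_hominin_er` that introgresses into
Denisovans. Every model carries a Neanderthal pulse into the OOA ancestor,
a Denisovan pulse into the Oceanian ancestor and symmetric continuous
migration between the African/European, European/East-Asian and
Papuan/Australian pairs. The variants add: a non-introgressed "basal
Eurasian" modern ghost admixing into Europeans (B); a second Neanderthal
(C) or Denisovan (D) pulse into the Asia-Pacific ancestor; or an archaic
ghost Xe pulsing into the Asia-Pacific ancestor, with Xe a Neanderthal
sister (E), a Denisovan sister (F), an outgroup of both (G), or the product
of a Neanderthal×Denisovan admixture event (H). E and F are represented
literally as the H structure with the Denisovan fraction of the Xe origin
pinned to 0 or 1, so the three models share one event list and differ only
in one prior.

Internal time unit is generations; configuration in years converts at 29
years/generation. Ordering constraints (e.g. the archaic split predates
the modern-human/archaic split) are encoded explicitly as predicate pairs
and enforced by rejection resampling of whole prior draws — no clipping —
so constrained marginals are exact.

### Priors and point values

Published posterior means and 95% credible intervals exist for the time
and fraction parameters of models F and H, but the priors and effective
sizes behind them are not available. Defaults are therefore:

* split/pulse **times**: per-parameter log-uniform priors wide enough that
  each reported 95% credible interval is interior to its prior (e.g. the
  African/OOA split over 50–250 kya-equivalents in generations);
* **effective sizes**: log-uniform on [100, 100 000] diploids;
* archaic **pulse fractions**: uniform [0, 0.2]; the Xe-origin Denisovan
  fraction uniform [0, 1]; the basal-Eurasian (modern) admixture fraction
  uniform [0, 0.5];
* **migration rates**: log-uniform on [1e-6, 1e-3] per generation.

For simulations "at the posterior means" (`posterior_means`), time and
fraction parameters use the published posterior means; effective sizes,
which the published table omits, use fixed point values chosen once from
standard human-demography literature (African 24 000; European, East Asian
and Indian 10 000; Andamanese, Papuan, Australian 5 000; archaic branches
2 500–3 000; OOA internal ancestors 5 000; deep ancestors 15 000) and
symmetric migration at 2.5e-5/generation. These nuisance values shift the
absolute magnitude of predicted D statistics (see Limitations).

## Simulation to the joint SFS

`abcdl.coalsim` translates a model plus one parameter draw into an msprime
demography (population splits, mass-migration pulses, admixture origins,
symmetric migration) and simulates independent regions — at full scale
9 643 regions totalling 651 Mb; a `scale` factor shrinks the region count
for desk-scale work. One diploid is sampled per population (nine sampled
populations), so the joint SFS is a 3^9 array of derived-allele-count
combinations. Mutations use a binary infinite-sites model, which makes
every site biallelic with a known ancestral state, and recombination is
uniform at 1e-8/bp/generation.

The genome-wide mutation rate is drawn per simulation from
N(1.61e-8, 0.13e-8) truncated at zero and scaled per region by the callable
fraction, `mu_r = mu * L_c / L_r`. A per-region redraw is available
(`mu_per_region=True`); the per-simulation draw is the default because the
rate uncertainty being propagated is a genome-wide calibration uncertainty,
not independent region noise.

Monomorphic corner cells (all-ancestral, all-derived) are recorded but
excluded from summary vectors: the all-derived corner is dominated by
polarization error on real data and neither corner carries model contrast.
The included-cell total therefore equals the number of polarized
segregating sites, which is checked exactly against the simulator.

## D statistics and F4 ratio

`abcdl.dstats` implements frequency-based Patterson statistics on
derived-allele frequencies (with one diploid per population, frequencies
are {0, ½, 1}): f4 = mean (w−x)(y−z) and
D = Σ(w−x)(y−z) / Σ(w+x−2wx)(y+z−2yz), with an `Ancestral` pseudo-
population (frequency 0 everywhere) usable as outgroup, matching the use
of inferred ancestral alleles. Sites missing in any member of a quadruple
are dropped listwise. Standard errors use a Busing-style weighted
delete-one-block jackknife over contiguous physical blocks (default 555),
weighted by per-block site counts; with equal weights it reduces exactly to
the textbook delete-one jackknife.

Introgression fractions are fitted to an observed D vector (five standard
quadruples) by simulation: the squared distance between observed and
simulation-mean D is minimized over the free fraction(s), with bounded
scalar minimization in 1-D and bounded L-BFGS-B in 2-D. Every objective
evaluation reuses the same simulation seed sequence (common random
numbers), making the objective deterministic and the optimizer stable at
modest replicate counts.

## Network summaries (SS-DL)

`abcdl.dlsum` trains four-layer feedforward networks (input, two hidden
layers, output) on simulated spectra. The classifier head is a softmax
over model labels; the regressor head is linear, one output per parameter,
with targets z-scored against the training draws. Defaults: hidden widths
input/3 and input/9 (geometric compression of the ~3^9-cell SFS),
ReLU activation, Adam with minibatches, early stopping on an internal
held-out split with best-weights restore. Exact layer widths and the
training algorithm are contracts of convenience, not of substance — the
meaningful contracts are the held-out metrics the tests assert (e.g.
near-perfect separation of a 4-fold mutation-rate contrast, held-out
correlation > 0.9 for a strongly identified parameter).

Inputs are normalized by dividing each spectrum by its included-cell sum
and z-scoring each cell against training statistics; this removes the
dependence on the total segregating-site count, which the mutation-rate
jitter deliberately randomizes (a raw-count mode is a flag).

**SFS-like noise injection.** Instead of white noise — inappropriate here
because SFS cells are strongly dependent — each training record is mixed
cellwise with a reference spectrum from observed data:
`(1−α)·sim + α·ref`, with α drawn fresh per record per epoch from
U[0, α_max], default α_max = 0.2. The reference comes from the half of the
observed cohort reserved for noise (below). With α_max = 0 training
reduces bit-identically to classical training. The frozen forward pass is
re-implemented in numpy, so `summarize` is a pure deterministic function of
stored weights, independent of the training trajectory.

## ABC

`abcdl.abc_core` standardizes each summary coordinate by its median
absolute deviation across simulations (robust to heavy tails), ranks by
Euclidean distance to the observed summary and retains the closest
`n_accept` (default 1 000 of 100 000), breaking boundary ties by simulation
index for determinism. Model posteriors come from an (effectively
unregularized) multinomial-logistic regression of label on summary over
the accepted set, evaluated at the observed summary, with a
rejection-frequency fallback on degenerate fits. Parameter posteriors use
the Beaumont local-linear adjustment with Epanechnikov kernel weights on
distance; bounded parameters are adjusted on a transformed scale chosen by
parameter class (log for times, sizes and rates; logit for fractions) and
back-transformed, so adjusted fractions cannot leave [0, 1]. Summaries
report weighted means and weighted 2.5/97.5 percentiles.

Validation uses a cross-validation confusion matrix: pseudo-observed
spectra simulated from each model are pushed through the full
summary→rejection→multinomial-logistic pipeline (networks and reference
tables built from training records only) with hard max-posterior
assignment.

## Observed data and the two-halves design

`abcdl.workbench` generates synthetic genotype cohorts (two diploids per
modern population, one per archaic) under any model, written as a VCF with
`AA` ancestral-allele tags, a 0-based half-open block BED and a ground-truth
sidecar; VCF coordinates are 1-based closed. Reading polarizes genotypes
against `AA` (flipping when `AA` equals ALT), drops unpolarizable or
all-missing sites with counters, and assigns jackknife blocks. The cohort
splits into two single-diploid-per-population halves: one supplies the
noise-injection reference spectrum, the other is the ABC target; the single
archaic individuals are shared by both halves. The simulator's own
half-spectra and the VCF→counts→SFS path agree exactly, by test.

## Problem sizes in tests and the acceptance script

Desk-scale runs shrink the simulated genome (typically 0.1–0.7 Mb over a
handful of regions) and the simulation counts (hundreds to ~1 500 per
model) so the whole suite runs on one CPU in minutes; these sizes are
stated in the tests themselves. The synthetic cohorts emulate panel shape
(population labels, sample counts, ancestral polarization, block structure)
but not sequencing artefacts, mapping bias, callable-mask structure or
real linkage maps — passing tests therefore demonstrate correctness and
internal calibration of the method, not field performance on real panels.

## Known limitations

* With the original prior/size table unavailable, posterior-mean
  simulations use the documented nuisance defaults above; predicted D
  values then reproduce the observed sign and ordering patterns but their
  magnitudes are sensitive to the unknown effective sizes and migration
  rates.
* At desk scale the spectra carry far less information than 651 Mb of
  sequence; the ghost-model variants (E/F/G/H) overlap substantially, and
  E and F are boundary cases of H by construction, so pseudo-observed data
  from one of them is legitimately assigned appreciable posterior mass by
  its neighbours.
* The SFS discards linkage information; models distinguished mainly by
  introgressed-fragment length structure are outside what this summary can
  separate.
* Archaic sampling ages default to co-sampling with moderns and are
  exposed as configuration.
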