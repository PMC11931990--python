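# Methods

This note records the models implemented by `agpfret`, their assumptions,
the defaults that matter, and the choices made where the underlying
experimental description left the design open.

## Förster model and multi-label combination (`fret_core`)

A single donor-acceptor pair at distance *r* transfers with efficiency
`E = 1/(1 + (r/R)^6)`. The Förster radius defaults to *R* = 50 Å, the
manufacturer value for Atto-495/Atto-565; it is a parameter everywhere.
Orientation effects (κ²), accessible-volume dye simulations and
time-resolved kinetics are out of scope: the dye position is approximated
by the labeled residue's Cβ with no linker correction, so predicted
distances carry a few Å of systematic uncertainty by design.

The labeling statistics drive the combination rules. At most one donor is
present per Agp2 dimer, at one of 14 cysteine sites with occupancy weights
`w_j ≥ 0, Σ w_j = 1` (uniform 1/14 by default — the measured incorporation
ratios give no reason to prefer any site, and surface accessibility is
similar across them). The per-monomer aggregate is therefore an
expectation over the single-donor ensemble, `E_i = Σ_j w_j E_ij`, which is
itself a valid efficiency in [0, 1]; implementing the aggregate as a plain
unweighted sum would exceed 1 for close poses and is physically invalid.
The two Agp1 acceptor channels then combine as independent sinks,
`E_total = 1 − (1 − E_1)(1 − E_2)`.

Averaging per-monomer first and combining afterwards is the default order
of operations. The alternative — combine the two channels per donor site,
then average over sites (`combination_mode="combine_then_mean"`) — is the
exact ensemble expectation for a single donor and is available behind a
flag; for the site geometries of interest the two differ by second-order
terms only.

Combined efficiencies are clamped to [0, 1] only to absorb floating error
up to 1e-12; larger violations raise.

Numerics: the inverse map `(1/E − 1)^(1/6)` loses precision by
cancellation as E → 1 (distances below ~5 Å); round trips are exact to
1e-9 relative above 5 Å and to ~1e-5 down to 1 Å. The inverse is defined
only on open (0, 1): a measured efficiency of exactly zero (the Agp1-PCM
control) has no distance.

## Spectroscopic estimators (`spectra`)

Mixture spectra are decomposed into the measured single-component
references by linear least squares on the mixture's wavelength grid
(references linearly interpolated; extrapolation is an error; collinear
references are a rank error). Coefficients are constrained nonnegative by
default (physical amplitudes; `scipy.optimize.nnls`), with an
unconstrained mode for diagnostics. On any noiseless linear combination of
non-collinear references the decomposition is exact.

Donor quenching: `E = 1 − (I_DA·A_D)/(I_D·A_DA)`.
Stimulated emission: `E = (I_AD·A_A − I_A·A_AD)/(I_A·A_DA)`.
Both read absorbances at the excitation wavelength (470 nm). The
acceptor-reference absorbance `A_A` is taken at the excitation wavelength
by default — the reading under which the stimulated-emission estimator is
algebraically exact for a linear photon budget (donor-absorbed quanta
transfer with probability E into the acceptor's emission channel); the
wavelength is configurable (`acceptor_reference_nm`) for users who prefer
a different convention. A negative stimulated-emission value is returned
as such (flagged by sign), indicating less acceptor emission than direct
excitation would produce.

Integration bands default to 500–560 nm (donor emission, maximum 530 nm)
and 575–650 nm (acceptor emission, maximum 595 nm) and are configurable;
band integrals are trapezoidal with interpolated endpoints. The
fluorescence ratio indicator defaults to F(590)/F(523) — the acceptor and
donor emission maxima — and both wavelengths are configurable.

Incorporation ratios divide the signal-band molar concentration by the
A280-derived protein concentration; the extinction-coefficient table ships
as a fixture, including the 0.7 factor by which protein-bound Atto-495
absorbs less than the free dye.

## Structures and distances (`structure_io`)

PDB v3.3 coordinate files are read and written through Biopython. The
flat atom table keeps chain, residue number/name, atom name and
coordinates; insertion codes are rejected, duplicate atoms are an error,
and alternate locations collapse to the highest-occupancy conformer (ties
by altloc letter). Which chains form the Agp1 dimer versus the Agp2 dimer
is explicit configuration (default A,B = Agp1; C,D = Agp2) and never
inferred from sequence. A per-protein integer numbering offset supports
structures in database numbering (the Agp1 expression construct carries
nine extra N-terminal residues). Label sites resolve to the Cβ atom, with
a logged Cα fallback for glycine or Cβ-less pseudo-residues.

## Screening (`screening`)

Per pose, predicted efficiencies at each acceptor position are scored
against the measurements by the sum of squared differences in efficiency
space (optionally in relative-distance space). The published per-model
score column could not be reproduced on any scale we tried (plain
efficiency-space SSD of the printed rows gives e.g. 0.088 where 0.65 is
printed); the packaged fixture carries the printed column verbatim for
reference, and all ranking in this package uses the recomputed SSD.

The three selection criteria are deliberately independent of absolute
labeling yields:

* **C1** `E(554) − E(122) > margin` (default margin 0; the largest and
  statistically significant contrast in the measurements).
* **C2** `E(554) − E(362) > margin` with default margin 0.05. The margin
  operationalizes "significantly lower": it is the scale of the reported
  measurement standard errors (0.02–0.06). This calibration is validated
  against the published verdicts themselves — it reproduces exactly the
  four finalist poses and the three training-pose outcomes (parallel,
  vertical, antiparallel), which neither a strict inequality nor a
  fold-ratio rule can do simultaneously.
* **C3** the domain-involvement pattern must match the truncation
  experiments: contacts on the Agp1 histidine kinase but not the Agp1
  PCM, and on the Agp2 PCM but not the Agp2 kinase/response-regulator
  module. Involvement is derived from the contact analysis; the domain
  boundaries default to Agp1 PCM 1–517 / kinase 518+, Agp2 PCM 1–501 /
  kinase 502+ (configuration, since exact construct boundaries are not
  part of the measured data).

The audit trail reports every model's three verdicts and the first
criterion that eliminated it; near-duplicate pose collapsing is left to
the user.

Occupancy robustness: donor weights are drawn log-uniformly per site on
[1, max_fold] and normalized, so the maximum pairwise occupancy ratio is
bounded by `max_fold` (40 by default) by construction. The distribution
family is a choice — any distribution with the same fold bound gives the
same qualitative conclusion for orderings backed by site-wise distance
dominance, since a weighted mean of pointwise-dominating values preserves
the order for every admissible weight vector. Per position pair the
reported statistic is the fraction of samples preserving the
uniform-weight ordering.

## Interface contacts (`interface_contacts`)

A contact pair is a cross-protein residue pair whose minimum interatomic
distance is at most the cutoff (3 Å default), reported once per residue
pair with that minimum. Heavy atoms only by default; an
`include_hydrogens` switch exists because several published per-pair
distances (down to 1.7 Å) are shorter than heavy-atom contact geometry
allows, suggesting a different atom selection there — the package exposes
the choice instead of silently emulating it, and exact per-pair distance
reproduction is not attempted.

Contact residues merge into sequence regions when at most `gap_threshold`
non-contact residues (default 15) separate consecutive members on the same
chain; singletons are reported as solo residues — in this system the solo
residues (e.g. Agp1 Lys554, Agp2 Arg83, Agp2 Asn439) are the candidates
for specifically evolved interactions. No single gap threshold reproduces
the published region partition exactly (one described boundary spans a
smaller sequence gap than a bridged gap inside another region), so the
grouping is presented as an explicit, configurable rule rather than a
replica. Conservation lookup maps an ungapped reference position through
the alignment gaps and returns every sequence's residue at that column.

## Synthetic data (`synthetic_data`)

The generator reproduces the study conditions where they are stated and
otherwise uses fixed, documented choices:

* **Toy structures** two parallel rod-like chains (Cα+Cβ pseudo-residues,
  3.8 Å rise — the canonical Cα spacing, 11 Å chain separation), residues
  spanning the real label positions (Agp1 122–603, Agp2 29–647), CYS at
  label sites. Optional pseudo side-chain atoms give the contact stage
  realistic atom multiplicity. A geometry seed applies a rigid transform
  only, preserving all internal distances.
* **Reference pose** the Agp1 rod crosses the Agp2 rod perpendicularly,
  its chain-A position 554 placed 45 Å from the Agp2 chain-C position-277
  donor site. This reproduces the qualitative measured pattern (position
  122 far from all donors, 554 closest) and makes every 554 distance
  dominate the matching 122 distance site by site, the premise of the
  robustness acceptance check.
* **Decoys** uniformly random orientations, ligand centroid placed at
  40–400 Å from the receptor centroid, rejection of poses with
  inter-protein atoms closer than 2 Å; deterministic per seed.
* **Measurements** per position, the mean ± SE of n Gaussian replicate
  draws around the noiseless prediction (defaults n = 4, per-replicate
  sd 0.03, matching the reported four-measurement means with SE
  0.02–0.06). Draws are clamped to [0, 1]; at this noise scale the
  clamping bias is negligible except for efficiencies within ~2 sd of the
  bounds, where it biases very small efficiencies slightly upward.
* **Spectra** Gaussian bands at the reported maxima: donor absorbance
  500 nm with the 475 nm satellite of the protein-bound dye, donor
  emission 530 nm, acceptor absorbance 565 nm plus a 470 nm band so the
  acceptor is directly excitable, acceptor emission 595 nm; widths
  15–30 nm. The mixture emission implements the linear photon budget
  (donor emission scaled by 1 − E; transferred quanta added to the
  acceptor channel), so both spectroscopic estimators recover the ground
  truth exactly without noise. `noise_sd` is additive Gaussian noise as a
  fraction of each spectrum's peak.

The generator's noiseless efficiencies are produced by the same
screening/Förster code path used for analysis, so a change to R (or to the
combination rule) propagates identically to truth and prediction — there
is deliberately no second Förster implementation to drift.

**What passing synthetic tests does and does not show.** The toy rods have
correct label-site topology and rigid-body geometry but none of the real
proteins' shape, so synthetic results validate the pipeline's mathematics
and ranking behaviour (pose recovery at the measured noise scale, ordering
robustness, contact bookkeeping), not the biological conclusions for real
coordinates; those depend on the docking models themselves.

## Problem sizes

Default test and acceptance runs use ensembles of 20 poses (1 true + 19
decoys) over 50 replicates for pose recovery, 1000 occupancy-weight
samples at 40-fold range for robustness, 100 complexes for
truth/prediction consistency, 50 random complexes against a brute-force
contact oracle, and 500 noisy spectra trials for estimator error — sizes
at which all statistics in question are stable from run to run.
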