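# Methods

This note records the models, defaults, numerical choices, and known
limitations of the package, in the order the pipeline runs them.

## Structures and selections

Structures (PDB/mmCIF, parsed with gemmi) are addressed by author chain id,
author residue number, and insertion code — the numbering used in residue
labels such as E60 or K694. Alternate locations are collapsed on load: the
conformer with the highest occupancy wins, ties broken by the
lexicographically smallest altloc id, so every downstream geometry is
single-conformer and deterministic. Multi-model files keep one model
(index 0 by default; a parameter selects others, e.g. for two-ring
depositions). Waters and other HETATM entities are retained but flagged and
never enter selections; hydrogens never enter geometry (cryo-EM models are
heavy-atom). Selections resolve to a reproducibly ordered atom list —
(chain, residue, insertion code, then N < CA < C < O < other names
alphabetically) — and residues missing a requested atom contribute what
they have and are reported in a skip list rather than failing the run.

Crosslinkable sites are every lysine plus each chain's first polymer
residue (the N-terminal primary amine), restricted to residues with a CA
atom, since a lysine-reactive NHS-ester crosslinker (DSBU-class) labels
exactly those amines.

## HDX uptake and differencing

Exchangeable amides per peptide follow common HDX practice: the N-terminal
residue is excluded (back-exchanges within seconds) and prolines are
excluded (no amide hydrogen), so `n_exch = (n−1) − #P at positions 2..n`.
The experimental reports this rule encodes do not state their exact
convention, so it sits behind a single named rule id in `HdxConfig`;
coverage percentages computed from it are rule-dependent to a few percent.

Uptake is the intensity-weighted centroid of the envelope on the neutral
mass axis (`z·(Σ mz·I/ΣI − m_proton)`) minus the undeuterated control's
centroid; no back-exchange correction is applied, and percent deuteration
normalises to the theoretical maximum uptake `n_exch · 1.006277 Da`, so
noisy values may slightly exceed [0, 100]. Condition differences are
per-(peptide, timepoint), replicates averaged (SD carried), significant iff
strictly greater than 0.4 Da in magnitude; tables are ordered N→C by
peptide start. Charge states of the same peptide are analysed separately,
never merged.

## EX1 bimodal deconvolution

Bimodal envelopes are fit on the charge-deconvoluted mass axis as two
Gaussians with free means and areas and one shared width, by bounded
least squares (`scipy.optimize.least_squares`, log-parameterised σ).
Initialisation is deterministic — means at the 25th/75th intensity-weighted
mass percentiles, σ at half the intensity-weighted SD, areas split at the
percentile midpoint — plus three more fixed starts (low-dominant,
high-dominant, symmetric split). The lowest residual wins; solutions within
2% relative residual of the best are treated as equivalent and the
least-mixed one is preferred, a parsimony tie-break that keeps an
effectively unimodal envelope from being reported as an arbitrary 50/50
split.

When the winning components are unresolved (separation ≤ 2 shared widths)
the envelope is a single subpopulation, and the fit is re-expressed from
the one-Gaussian solution with the whole area on one side: the closed side
if the centroid lies in the lower half of the recorded mass window, the
open side otherwise. HDX spectra are recorded over the peptide's full
possible deuteration range, so the window midpoint separates
mostly-protected from mostly-exchanged envelopes. `f_open` is always the
high-mass area fraction and is invariant to uniform intensity scaling.

Modality calls compare the one- and two-Gaussian fits by small-sample
corrected AIC (k = 4 vs 6 including the variance parameter) and
additionally require the fitted means to be separated by more than 2σ —
below that separation two components are not resolvable regardless of the
information criterion. Both thresholds are arguments.

Transition kinetics fit `f(t) = f_inf − (f_inf − f0)·exp(−k_open·t)` with
box constraints `f0, f_inf ∈ [0,1]`, `k ≥ 0`, from three deterministic rate
starts (1/median, 1/max, 1/min of the positive timepoints); a flat series
is fit exactly by `f0 = f_inf` with k unidentifiable, which is the stated
degenerate behaviour.

## Crosslink mapping

Each residue-pair identification is enumerated over all canonical chain
pairs of the assembly (both orientations of a heterologous pair evaluated,
shorter kept). The structural interpretation is the minimum-distance
assignment — the standard satisfiability convention on a homo-multimer
where the identification cannot distinguish intra- from intermolecular —
with ties within 0.01 Å resolved intra-first, then lexicographically.
A link is satisfied iff its best distance is ≤ 30 Å (inclusive, cutoff and
boundary convention config-exposed) **and** its Cα–Cα vector is clash-free:
the segment is sampled every 0.5 Å with 10% margins at each end, and any
heavy atom outside the linked residues ±1 neighbour within a 2.0 Å probe
radius is a clash. These parameters approximate "the vector passes directly
through the domain" while tolerating surface grazing, and all are
config-exposed; the sampled test agrees with the exact point-to-segment
computation whenever the step is ≤ 0.25 Å (verified in the tests).
Satisfaction fractions count unique residue pairs by default, with
CSM-count weighting available, since published fractions do not state the
weighting. Condition-specific links are a plain set difference on residue
pairs. Region breakdowns use a residue-range table defaulting to the
ARM (60–402), SAM (403–549), TIR (561–701) docking ranges.

## Superposition and domain motion

Superposition is Kabsch via SVD of the cross-covariance with the sign of
the smallest singular direction corrected so the rotation is always proper
(det +1), never a reflection — degenerate collinear point sets included.
Rotation magnitude is `arccos((tr R − 1)/2)`, clamped, in [0°, 180°]; no
Euler decomposition is attempted. Atom pairing across structures is by
(chain, residue, insertion code, atom name) identity after an optional
chain-mapping table (equivalent protomers may be labelled differently
across depositions); unpaired atoms are dropped pairwise and reported.
Domain motion superposes state B on state A via the reference selection,
then measures the residual rotation of the mobile selection; marker
displacements are Euclidean distances after reference alignment, and the
screw component is the mobile-centroid shift along the residual rotation
axis. Near-identity rotations are reported at the conditioning limit of the
trace formula (~1e-5 degrees).

## Synthetic data: what it emulates, and what it does not

Envelopes: each deuteration subpopulation is a binomial distribution over
`n_exchangeable = 20` sites (deuterium increment 1.006277 Da, proton mass
1.007276 Da), convolved with a coarse averagine-like 3-peak natural-isotope
profile (geometric ratio `5.5e-4 ×` nominal mass, here 800 Da) and a
Gaussian instrument peak of σ = 0.4 Da, rendered at charge 2 on a uniform
m/z grid. Subpopulations are normalised to unit summed intensity before
mixing, so noiseless mixtures are exactly linear and total 1.
Multiplicative Gaussian intensity noise (CV 2% by default, 5% in the
recovery grids) is applied last. The EX1 series uses the five labelling
timepoints of the emulated design (10 s, 30 s, 1 min, 5 min, 30 min) with
open-state weight following the first-order law; default rates
(0.01 /s activator-like, 0.001 /s substrate-like, f0 = 0.05) put the
transition inside that window. Binomial widths depend on the mean, so
recovery tests place the two means symmetrically about half-deuteration
(e.g. 6.5/13.5 Da), where both subpopulations have equal width — the
configuration the shared-σ model assumes. Not simulated: chromatography,
peptide overlap, back-exchange (the emulated protocol applies no
correction), or real isotope fine structure.

Ring assembly: n identical CA-only protomers — a 40-residue idealised helix
(rise 1.5 Å, twist 100°, radius 2.3 Å) with lysines every 4th residue and
residue 1 placed exactly at the ring radius so equivalent-atom chords obey
`2R·sin(π/n)` in closed form. The helix spans ~60 Å, so large-gap residue
pairs violate the 30 Å restraint even within one chain, giving a natural
decoy pool. Crosslink sampling classifies candidate residue pairs by their
minimum over all chain-pair placements: true contacts at ≤ cutoff − 2·SD
with a clash-free shortest placement, decoys at > cutoff + 2·SD. The
2-SD margins (SD = 1 Å) make the downstream classification reproduce the
truth labels exactly, so label-recovery tests are exact rather than
statistical. Passing them shows the mapping logic is correct, not that real
crosslink data — with ambiguous identifications near the cutoff,
conformational mixtures, and false positives — would classify this cleanly.

Problem sizes were chosen so the full pipeline and its recovery grids run
in seconds: 9×20 envelopes for f_open recovery, 100 replicate series for
noisy rate recovery, 1,000 random point sets for the superposition oracle,
an 8-protomer ring with 10 crosslinks for mapping.

## Known limitations

- The two-Gaussian model absorbs binomial asymmetry into its shared width;
  at extreme mixing fractions with strongly unequal subpopulation widths
  the recovered f_open can be biased by a few hundredths.
- Crosslink distances are Euclidean Cα–Cα only; no solvent-accessible
  surface distance, and no FDR modelling of the identification step.
- Rigid-body motion assumes the mobile selection moves as one body; hinge
  or melting motions show up only as elevated residual RMSD.
- The unresolved-envelope side assignment relies on the recorded mass
  window spanning the peptide's full deuteration range; truncated windows
  would bias it toward the closed side.
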