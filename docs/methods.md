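# Methods

## Scope and data model

All analyses operate on a single in-memory container, the
`StructureEnsemble`: an ordered list of models over a constant atom topology
(same `(chain, resid, icode, resname, atom_name)` sequence in every model).
Cryo-EM depositions of one experimental condition and MD trajectory frames
exported as sequential PDB models are both instances of this container, so
the distance machinery is shared between the state-comparison and the
trajectory analyses. Coordinates are angstroms throughout; residues keep the
author numbering of the source file with no renumbering. Native binary
trajectory formats (DCD/XTC) are deliberately out of scope — frames are
consumed as multi-model PDB text, which keeps the toolchain format-exact and
dependency-free.

PDB ingestion keeps `ATOM` records (plus `HETATM` on request, needed for
ions and waters), always drops hydrogens (all geometry here is heavy-atom),
and keeps only blank or `'A'` alternate locations, dropping others with a
logged count — a deterministic approximation of the highest-occupancy
convention. Writing emits fixed columns with coordinates to three decimals;
a coordinate ≥ 10000 Å cannot be represented in the 8-column field and is an
error rather than silent truncation.

## Salt-bridge proxy distance

For a residue pair with one acidic (Asp/Glu) and one basic (Lys/Arg/His)
member, the interaction proxy is the minimum Euclidean distance over the
cross product of side-chain terminal charged atoms:

    Asp: OD1, OD2   Glu: OE1, OE2   Lys: NZ   Arg: NE, NH1, NH2   His: ND1, NE2

Carboxylates and guanidinium groups offer chemically equivalent atoms, so a
single-atom choice would be arbitrary; the minimum over all listed pairs is
the standard salt-bridge convention, deterministic, and never larger than
any single-atom convention. Histidine is included with both ring nitrogens
for generality. Pairs that are not one-acid-one-base are computed under the
same generic terminal-atom rule with a logged warning.

Chain handling: `intra` mode (default) uses exactly the chains named in the
pair spec; `min_over_chain_pairs` evaluates the first residue in every chain
that contains it against the second residue in every chain and returns the
global minimum — relevant for homotetramers where a contact could be
inter-subunit and the assignment is not known a priori.

Per-condition statistics pool all models of all structures of the condition
with equal weight per model (not per deposition); mean and sample standard
deviation (n−1 denominator, sd = 0 for a single model) are reported with n.
Condition comparison is the signed difference of condition means per pair.
A 4.0 Å cutoff classifies a distance as a formed or broken contact
(boundary inclusive); this threshold is qualitative labelling only and never
enters the statistics.

## Ca²⁺ coordination sites

A coordination site is evaluated per ion (HETATM atoms whose atom name
matches the configured ion set, default `CA`): the shell is every oxygen
atom within the distance cutoff, and the site qualifies when the oxygen
count is within [min, max] and the mean shell distance is within the cutoff.
Defaults encode the generic first-shell geometry of protein-bound calcium:
4–8 oxygens within 2.5 Å. Because the shell is defined by the same cutoff,
the mean condition is automatically satisfied; the operative rule is the
count of oxygens within 2.5 Å, the strictest reading consistent with both a
per-oxygen and an average-distance phrasing. Oxygens are selected by element
only — carboxylate, carbonyl, hydroxyl and water all count; waters can be
excluded by flag (default: included). Trajectory occupancy tracks a site by
ion atom identity (topology is constant), reporting the fraction of frames —
optionally restricted to post-onset frames — in which the site qualifies.
Spatial clustering of transient sites is a non-goal.

## Superposition RMSD and stability onset

`kabsch_superpose` is implemented from first principles: subtract centroids,
form the 3×3 cross-covariance, take its SVD, and correct the sign of the
smallest singular direction so the rotation is proper (det = +1). The
returned RMSD is the global minimum over rigid transforms. The RMSD series
of a trajectory superposes every frame onto a reference frame (default:
frame 0, configurable) over a configurable atom selection (default: Cα of
non-hetero residues); times are frame index × cadence (default 0.2 ns).
The reference frame's value is set to exactly zero.

The equilibration criterion is a sliding-window slope test: the onset is the
first frame *i* such that the least-squares slope of the RMSD values over
frames [i, i+window) is within ±slope_tol. Defaults: window 50 frames
(10 ns at the default cadence), slope_tol 0.05 Å/ns. If no window is flat
enough the onset falls back to `n_frames − window` with a logged warning, so
downstream averages always have `window` frames to work with. The criterion,
window and tolerance are this package's construction — equilibration
detection has no single canonical rule — and both parameters are exposed in
every interface. The onset is non-decreasing as the tolerance shrinks by
construction (first-index rule over a shrinking feasible set).

Post-onset pair distance statistics reuse the salt-bridge machinery per
frame and the same mean/sd/n reporting, labelled by the trajectory's
condition tag (e.g. NaCl vs CaCl₂).

## Conservation profiling

Input is a fixed aligned FASTA (alignment computed upstream) plus a
two-column id→group TSV. Per column and group: the modal residue is the most
frequent non-gap character (ties break to the lexicographically smallest,
logged; gaps never win), and identity % divides the modal count by the full
group size, gapped sequences included in the denominator — the convention of
standard alignment viewers. Scaffold windows are maximal runs of ≥ min_len
consecutive columns at or above the identity threshold (default 70%, 3
columns), reported as half-open 1-based intervals. Fingerprint positions
compare a focal against a contrast profile over the same columns: a hit
requires focal identity ≥ t_high (default 80%) and either a different
contrast modal residue or contrast identity < t_low (default 50%). The
thresholds are package defaults exposed in config; column coordinates are
alignment columns, and mapping to structure numbering is left to the caller.

## Inactivation kinetics

Traces are uniformly sampled (default 10 kHz), with the pulse window
(default 60 ms) inside the trace. The residual current is the ratio of
window means — mean current over the last `edge_ms` (default 5 ms) of the
pulse divided by the mean over the first `edge_ms` — rather than two single
samples; the window mean is the robust reading of "current value at the
end/beginning" and both conventions agree on noiseless data. The ratio is
computed on signed currents (so it is invariant under overall scaling and
sign flip) and refuses denominators below a 1 pA floor.

The time constant comes from a least-squares fit of
`I(t) = I∞ + (I₀ − I∞)·exp(−(t − t_pulse)/τ)` over the pulse window
(`scipy.optimize.curve_fit`), initialized from the data: I∞ ← end-window
mean, I₀ ← start-window mean, τ ← log-linear regression of |I − I∞_init|.
A fit is reported only when the optimizer succeeds and τ falls in
(0.1 ms, 10 × pulse duration). Traces that do not actually decay return
`converged = False` with τ absent; the operative test is that the decay
amplitude |I₀_init − I∞_init| must exceed three times a noise-scale estimate
taken from first differences (σ ≈ sd(ΔI)/√2 — at 10 kHz the decay
contributes negligibly to successive differences). An optional blanking of
the first portion of the pulse (default off) is available for real traces
with capacitive transients; synthetic traces do not need it. Group summaries
report mean ± standard error; hypothesis testing is out of scope.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of its spec, seed included — identical
specs give byte-identical artifacts. Coordinates are quantized to 0.001 Å
(the PDB field precision) *at generation time*, so written files round-trip
exactly and planted values are realized exactly in the emitted coordinates.

- **Bridge ensembles**: per model and pair, minimal residues (backbone CA
  plus the terminal charged atoms) are placed axis-aligned so the *minimum*
  terminal-atom distance — the measured quantity — equals a draw from
  Normal(mean, sd) truncated above 0.5 Å; all non-minimal atom pairings are
  strictly longer by construction. Decoy atoms sit ≥ 10 Å from every pair
  atom. Each pair lives in its own spatial block (and, where a residue would
  be shared between pairs, its own chain — one residue cannot occupy two
  planted positions at once).
- **Trajectories**: the planted RMSD profile (linear rise to the changepoint
  frame, then a noisy plateau) is realized by displacing two mirror clusters
  of k Cα atoms at ±x by ±u(t) inside a static anchor frame. The net
  translation is zero and the cross-covariance with the reference stays
  symmetric positive definite, so the optimal rotation is exactly the
  identity and the aligned RMSD equals √(2k/N)·u(t) exactly (N = all
  selected Cα atoms). Pair distances follow their own per-frame process
  (mean, fluctuation sd, optional pre-onset drift) with backbone atoms held
  static so they do not perturb the RMSD plant. Ground-truth series are
  returned alongside the frames.
- **Coordination shells**: one Ca²⁺ HETATM at the origin, oxygens at the
  planted radii in random directions with ≥ 1.5 Å mutual separation, decoys
  beyond 5 Å.
- **Alignments**: per-column residue counts are constructed exactly (no
  sampling): default columns are fully conserved, fingerprint columns are
  100% one residue in the focal group and 100% a different residue
  elsewhere, variable columns cycle residues so no identity is high, and
  per-column overrides realize an exact identity level with distinct filler
  residues or gaps.
- **Current traces**: the single-exponential model sampled at the configured
  rate with additive Gaussian noise over the pulse and a zero-current
  baseline before it; the seed is recorded in the CSV header.

The packaged scenario bundle fixes the study conditions: a "TRPV6-like"
two-condition set (HLH–TDh 12 Å apo → 4 Å bound; ARD6–HLH 15 Å in both;
S2S3–TDh 5 → 10 Å), a "TRPV5-like" set (ARD6–HLH 4 Å in both; HLH–TDh ≥
12 Å in both; S2S3–TDh 8 → 4 Å), Na⁺/Ca²⁺ trajectory pairs in which only
the TRPV6-like channel's HLH–TDh contact forms under Ca²⁺, and trace sets
for the two wild-type phenotypes (τ ≈ 10 ms fast-inactivating vs
non-inactivating). Two structures of four models per condition with 0.5 Å
scatter keep the per-condition n comparable to the handful of depositions
available per state while remaining cheap.

This geometry is idealized: residues have no full side chains, no sterics,
no periodic boundaries, and the RMSD plant exercises a single collective
motion. Passing tests therefore demonstrate the correctness of the
*measurement machinery* — distance minimization, statistics, superposition,
changepoint and fit recovery — not the realism of any force field or the
biology of the real channels.

## Numerical choices and problem sizes

- Sample sd uses ddof = 1; n = 1 reports sd = 0.
- Contact classification is boundary-inclusive (d = cutoff ⇒ formed).
- Modal ties and dropped altlocs are logged, never silent.
- The changepoint studies use 500-frame trajectories with the change at
  frame 150 and 100 replicates; fit-recovery studies use 100 noisy traces at
  5% amplitude noise. These sizes give stable recovery rates while keeping
  the full test suite and the acceptance script in the tens of seconds.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  acceptance script derives every sub-seed from its `--seed` argument.

## Known limitations

- mmCIF is not parsed; convert upstream.
- No detection of inter-chain contacts beyond the `min_over_chain_pairs`
  minimum; per-subunit breakdowns require separate pair specs.
- The stability rule assumes an RMSD series that becomes flat; oscillatory
  or drifting-forever trajectories trigger the fallback window.
- τ fitting assumes a single-exponential decay; bi-exponential kinetics will
  converge to an effective τ without warning.
- The coordination rule counts oxygens only; it does not distinguish
  bidentate carboxylates or score geometry beyond distances.
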