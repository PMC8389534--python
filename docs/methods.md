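# Methods

## Consensus docking model

The toolkit treats a docking study as a pose pool with provenance: each
pose is labelled `ENGINE_m_n`, where `m` is the engine's own rank for the
pose and `n` indexes the refinement run that produced the deposited
coordinates (`n = 1–5`: distance-restrained relaxation; `n = 6–10`:
distance- plus position-restrained). Pool arithmetic is
`Σ_engines poses_returned × 10`; engines may return fewer than the
requested five poses, so a five-engine study yields 250 poses at full
strength and e.g. 210 when one engine returns a single pose.

Consensus selection assumes that a correct binding mode is rediscovered by
several engines and survives refinement, so it forms a populous, tight
cluster of the pool, whereas engine-specific artifacts scatter. The
pipeline therefore never consults docking scores: population and geometric
tightness carry all the signal.

### Pairwise dissimilarity

All-pairs RMSD over the heavy atoms shared by every pose (atoms matched by
chain/residue number/insertion code/atom name; atoms missing anywhere are
dropped everywhere and logged). Each pair is superposed by the
least-squares rigid transform before measuring. Superposition is the
conservative choice: refined poses no longer share an exact receptor
frame, so in-place RMSD would mix binding-mode differences with global
drift. A `superpose=False` flag provides the in-place variant. Hydrogens
never enter RMSD or contact selections (protonation differs between
refinement outputs); they are retained on read and used only for
hydrogen-bond angles.

Homodimeric complexes need care: two sequence-identical chains must not be
silently permuted (an open and a closed conformer of the same protein are
different objects). Chain permutation is therefore *opt-in* via
`permutable_groups`; when declared, all allowed permutations are evaluated
and the minimum-RMSD one is returned. Mirror solutions are excluded (the
rotation determinant is +1 by construction).

### Clustering and model selection

Agglomerative clustering (scipy; `average` linkage by default, `complete`
and `single` exposed — cluster counts can depend on the convention, so it
is config-visible). The Kelley penalty selects the level: for level `k`,
the spread of each multi-member cluster is its mean pairwise RMSD; level
spreads (averaged over multi-member clusters) are normalized linearly
across levels onto `[1, P−1]`, and `penalty(k) = normalized_spread(k) + k`.
Levels whose clusters are all singletons carry no spread and are excluded
from normalization. Ties prefer the smaller `k`; an all-zero matrix yields
a degenerate profile with `N = 1` and a warning.

Cluster statistics per cluster: population, centroid member (minimum mean
RMSD to co-members; ties resolve to the lexicographically first label),
average and standard deviation of member–centroid RMSD, and the RMSD of
each centroid to the main cluster's centroid. The main cluster is the most
populated; a population tie prefers the tighter cluster, then the smaller
cluster id. The consensus pose `Q` is the main cluster's centroid member.
Component analysis reports per-engine member counts with half-up integer
percentages (raw fractions retained in the machine output).

## Interface and trajectory observables

* **Contacts**: residue pairs across a declared two-sided chain partition
  with minimum heavy-atom distance ≤ cutoff (default 5 Å, the conventional
  interface-contact radius). Detection uses a k-d tree and is validated
  against an all-pairs oracle in the tests.
* **Native contacts**: the contact set anchored on hot-spot residues —
  entries of a user-supplied ΔAff table exceeding a threshold (default
  10 kcal/mol) on either side, paired against all residues of the other
  side. ΔAff values are inputs; computing them (alanine scanning, MM-GBSA)
  is explicitly out of scope.
* **Retention**: per-frame fraction of native pairs still within the
  cutoff. The fraction is 1 at the frame that defined the native set by
  construction.
* **Hydrogen bonds**: donor–acceptor heavy-atom distance ≤ 3.5 Å and, when
  hydrogens exist on the donor, best D–H···A angle ≥ 120°; without
  hydrogens the distance criterion alone applies and the output is
  flagged. Donors/acceptors come from per-residue templates (backbone N/O
  always included); pairs within the same or an adjacent residue of one
  chain are excluded as covalent neighbours. The thresholds are common
  literature defaults and are parameters, not constants — absolute counts
  from other software with other defaults are not expected to match.
* **Salt bridges**: Asp/Glu carboxylate O to Lys/Arg/His side-chain N
  ≤ 4.0 Å, counted once per residue pair.
* **RMSD time series**: each frame superposed onto a chosen reference
  frame (Cα by default) before measuring.
* **RMSF**: frames are superposed to an iteratively refined mean structure
  (initial fit to frame 0, then two refinement passes — the reference
  convention is stated because no standard exists); per residue, the RMSF
  is the root-mean-square deviation of its selected-atom centroid from the
  time-average position.

## Composite assembly

A graft step superposes the Cα atoms of a shared domain of the incoming
structure onto the counterpart domain in the scaffold (side chains differ
between structural contexts, so Cα-only fitting is deliberate), applies
the rigid transform to the whole incoming structure, and appends the
requested chains under deterministic next-free-letter ids. Internal
geometry is preserved exactly (rigid transform); the fit RMSD of every
step is logged and a fit above 2 Å warns without failing. Recipes chain
grafts to build multi-protein units; a final report lists inter-unit
heavy-atom pairs below 2 Å. No steric relaxation is performed — clashes
are information, not errors.

## Synthetic data

The generator emulates the *structure* of a multi-engine docking study,
not its energetics:

* **Toy complex**: two-chain poly-alanine with ideal backbone internal
  coordinates (helix φ/ψ = −57/−47°, strand −139/135°) built by natural
  extension; chain B is chain A shifted 8 Å perpendicular to the helix
  axis, leaving closest heavy atoms at ~3–4.5 Å — a bound interface whose
  contacts sit well inside the 5 Å cutoff, as in a real complex.
  Optionally the middle residues become a Glu/Lys pair with side chains
  built toward each other (a planted salt bridge at ~3 Å).
* **Pose pools**: cluster centers are distinct rigid placements of the
  ligand chain forming a radial ladder — receptor–ligand separation
  differs by multiples of `inter_separation` (default 20 Å) between
  modes, plus a distinct ligand orientation per mode. Because no rigid
  motion changes a complex's internal receptor–ligand distance, any two
  centers stay ≥ separation/2 apart in superposed RMSD: separability of
  the planted structure holds in the clustering metric itself, by
  construction. Members add Gaussian jitter (`intra_spread`, default
  0.3 Å per coordinate) about their center; engine labels follow
  per-cluster proportions with unique `(engine, rank, protocol)` triples.
  Recovery of 3–14 planted clusters requires study-scale pools
  (~15 members per cluster, pools of 45–210): the Kelley penalty's `+k`
  term outweighs the final split in very small pools, which is a property
  of the penalty, not of the implementation.
* **Trajectories**: `stable` jitters all atoms (default 0.03 Å, small
  against the interface's contact-cutoff margin, so a bound complex stays
  bound); `dissociating` adds a monotone 2.5 Å-per-frame ligand
  translation, so native contacts can only break.

What passing on this synthetic data does **not** show: docking-engine
realism (no energetics, no conformational change), force-field-level
hydrogen-bond counts, or behaviour on structures with gaps, altlocs and
non-standard residues beyond the cases unit-tested in `structio`.

## Numerical choices and limitations

* Superposition via SVD (`scipy` `align_vectors`); identity comparisons
  are exact to ~1e-7, and the package's stated precision for superposed
  quantities is 1e-6 Å.
* Merge-distance ties in the agglomerative tree follow scipy's
  deterministic ordering; end-to-end runs are byte-reproducible for
  identical inputs and config.
* Altloc resolution keeps the highest-occupancy conformer (ties: first
  altloc id alphabetically). Waters and non-protein HETATM records are
  excluded on read.
* Residue identity is `(chain, resseq, icode)` throughout; insertion
  codes are supported.
* Percentages round half-up to match reporting conventions; raw fractions
  are preserved.
* The problem sizes used by the test suite and the acceptance script
  (6–12-residue chains, pools of 30–250) were chosen as the smallest
  scales at which every claimed property is exercised, including the
  study-design pool arithmetic of 250/210 poses.
* Out of scope by design: running docking engines or refinement servers,
  energy scoring or re-ranking, ΔAff/MM-GBSA computation, MD simulation,
  mmCIF output, and nucleic-acid/ligand chemistry.
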