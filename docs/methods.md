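# Methods

This note documents the models implemented in `gpcrstab`, the
parameter choices that matter, what the synthetic generators do and do
not emulate, and the design decisions taken where several readings
were defensible.

## Numbering and mutation labels

Sequence positions are 1-based.  Generic numbers follow the class-A
GPCRdb convention `tm.offset` with helix index 1–7 plus helix 8;
intracellular/extracellular tags (`ECL2`, `12.51`, …) are carried as
opaque strings and are never scored, because loop and terminus
positions are excluded downstream anyway.  The position ↔ generic
number table is an *input* (TSV: position, residue, generic_number);
TM-boundary inference and automatic alignment to the numbering scheme
are deliberately out of scope.  Mutation labels render as
`C360^7.45^N`, bridges as `A98^2.49^C/A140^3.38^C`; labels round-trip
through parsing.

## Knowledge lane

The rule table (TSV, packaged, user-overridable) lists one rule per
generic position: admissible wild types (`X` = wildcard excluding the
target residues themselves), target residues, role, and exemplar
structures.  A rule with two targets (3.40 I→V, A) emits two separate
candidates.  Applicable rules score exactly 1.0.  Sodium-pocket rules
(2.50, 3.39, 7.49) are *flagged* rather than removed by the
binding-pocket filter: the sodium site is an allosteric pocket
distinct from the orthosteric ligand pocket, but mutations there can
decouple signaling, which the flag surfaces to the user.

## Sequence lane

For alignment column *k* and residue *aa*,

    score_k(aa) = (C_k^max − C_k^aa) / N_MSA − C_k^aa / C_k^max.

Reading notes:

* `N_MSA` is the total number of rows in the alignment; gaps and
  non-standard letters are excluded from the residue counts but not
  from `N_MSA`, so heavily gapped columns are implicitly penalized
  through a small modal count.
* The score is −1 exactly when *aa* is modal, bounded above by
  (N−2)/N < 1 (attained at `C_aa = 1`, `C_max = N`), and strictly
  decreasing in `C_aa` at fixed (N, C_max).  `scripts/acceptance.py`
  verifies the bound by exhaustive enumeration up to N = 50.
* Gly adjustment: when the wild type is glycine and Gly is not modal,
  the score is doubled (glycine destabilizes transmembrane helices).
  The doubling is applied per MSA, before averaging, and doubled
  scores are not clipped; the matrix range is [−2, 2] after
  adjustment.  In the per-position score matrix the adjustment lives
  in the G column of non-Gly-modal rows, so a wild-type Gly lookup
  sees the adjusted value.
* The net matrix is the unweighted cell-wise mean of 1–5 per-MSA
  matrices; positions absent from an alignment contribute nothing to
  that cell (mean over the matrices that cover it).  Per-MSA
  regression weights are out of scope.
* Candidates: annotated TM positions ranked by the wild type's net
  score (only strictly positive scores propose candidates); each
  selected position proposes the modal residue of every contributing
  MSA (deduplicated; modal ties broken by total count across MSAs,
  then alphabetically), truncated to `top_k` (default 40).

## Structure lane

The lane consumes a single-chain structural model (PDB or mmCIF via
biotite) plus the annotation.  The membrane frame defaults to the
principal axis of the TM Cα atoms (overridable); glycines use a
virtual Cβ reconstructed from backbone geometry for every Cβ-based
test.

Ionic-lock screen: unordered residue pairs with (i) sequence
separation ≥ 5 (excludes same-helix neighbours), (ii) both side chains
inward (Cβ radial distance from the bundle axis ≤ Cα's) and mutually
facing (each Cα→Cβ vector within 90° of the inter-Cβ vector), and
(iii) Cβ–Cβ ∈ [7.0, 10.0] Å.  Each hit proposes the four charged
pairs E-K, E-R, D-K, D-R in both site orders; a site whose wild type
already matches stays unmutated, so candidates near pre-existing
charges become single-site mutations.

Disulfide screen: separation ≥ 5, Cβ–Cβ ∈ [3.4, 4.7] Å, and a χ3
dihedral (Cβ–Sγ–Sγ–Cβ, with each Sγ placed at ideal bond geometry
tilted toward the partner) within ±30° of ±87°.  Thresholds are
config constants (`DesignConfig`, YAML-overridable).

Side-chain repacking: mutated sites plus the neighbour shell (any
heavy atom within 5 Å) are coarse-grained to a single centroid
pseudo-atom per side chain, placed from internal coordinates
(distance from Cβ and an effective radius per residue type — a Cys
centroid is sulfur-sized, a Trp centroid ring-sized).  A seeded
Metropolis search over 12 discrete χ states (150 steps, T = 1) with a
final greedy quench minimizes the pairwise interaction energy;
Gly/Ala have no rotamers and stay rigid.  The returned model is the
better of the search result and its starting point under the full
energy, so repacking never raises the surrogate folded energy.
The search is deterministic given the seed.

Energy surrogate: the acceptance contract is the folded/unfolded
comparison

    E_folded(mut) − E_unfolded(mut) < E_folded(wt) − E_unfolded(wt)

under a documented surrogate; absolute energies are arbitrary units
and are not comparable to any published force field.  Terms:

* electrostatic: formal side-chain charges (D/E −1, K/R +1, on the
  centroid or terminal charged atom), distance-dependent dielectric
  ε(r) = 4r, 12 Å cutoff;
* van der Waals: 12-6 Lennard-Jones on element-class radii scaled by
  0.9 (soft core), ε = 0.15, 10 Å cutoff, +10 cap per clashing pair;
  same-residue pairs, adjacent backbone-backbone pairs, and the side
  chains of cross-linked Cys pairs (Cβ–Cβ < 5 Å) are excluded as
  bonded;
* solvation: atomic solvation parameters (σ_C = +0.012,
  σ_N/O = −0.060 kcal·mol⁻¹·Å⁻²) times Shrake–Rupley accessible area
  (Fibonacci sphere, 100 points, probe 1.4 Å), computed internally so
  centroid pseudo-atoms participate with their effective radii;
* hydrogen bond: −2 kcal/mol distance well on N···O heavy-atom pairs
  (full weight 2.8–3.2 Å, zero at 2.4/3.6 Å, separation ≥ 2);
* contact (pmf): a packaged 20×20 statistical table applied per
  Cβ–Cβ contact < 8 Å, derived from a hydrophobicity outer product,
  plus a fixed −4 kcal/mol cross-link reward for Cys pairs at bonding
  distance.

The unfolded reference is a packaged per-residue constant: the
surrogate's own solvation of an isolated, fully exposed residue in
the same coarse representation.  Making the reference self-consistent
with the folded-state representation is essential — otherwise the
reference dominates the comparison and no mutation can ever be
accepted.  The energy function is pluggable
(`propose_structure_mutations(..., energy_fn=...)`).

Acceptance semantics: any charged-pair assignment that improves the
predicted folding free energy is emitted (each scored separately,
score = wtΔ − mutΔ > 0); the same mutation reachable through several
pairs keeps its best score.  In tightly packed toy bundles the
disulfide screen's hits frequently fail the energy criterion because
inserting two Cys side chains into a Gly-sized hole is sterically
strained — the screens and the energy filter are intentionally
independent stages.

## ML lane

Feature vector (fixed order, 40 components = 20 per residue state ×
{wt, mut}); the mutant residue is placed by the repacking search
before its blocks are computed:

* sequence block: hydrophobicity (Kyte–Doolittle), polarity
  (Grantham), formal charge, side-chain volume (Zamyatnin), reference
  accessible surface (Tien et al.), polarizability (Charton) —
  packaged published tables, named in the scale-file header and
  overridable;
* structure block: counts of polar/charged/hydrophobic/aromatic
  residue contacts (min heavy-atom distance < 5.5 Å, separation ≥ 2),
  residue solvent exposure, buried contact area (reference minus
  exposed), mean packing gap over contacts (void proxy), relative
  accessible surface;
* energy block: the surrogate's contact, electrostatic, van der
  Waals, solvation and hydrogen-bond interaction terms of the residue
  with the rest of the model, plus their total.

Benchmark assembly: stabilizing records give a +1 example and their
reverse mutation a −1 example (the reverse is approximated on the
forward-mutated model); remaining alanine-scan-style records give −1.
This mirrors the heavy imbalance of real panels (~8% positives).

Training: features are standardized with training-split statistics
only, and SVM class weights are inversely proportional to class
frequency — without both, the imbalanced benchmark collapses onto the
majority class.  The grid C, γ ∈ {0.2, 0.4, …, 50.0} (250 values per
axis, 62,500 cells; zero is excluded because C = 0 and γ = 0 are
invalid for an RBF SVM).  The grid γ is expressed *per feature
dimension* (effective kernel width γ/n_features on standardized
inputs) so the same grid stays meaningful for any feature-space size.
For each of 10 repeats the benchmark splits 65/35 stratified; each
cell's model is scored on the validation part by
PPV = TPR/(TPR + FPR); cells with TPR = FPR = 0 are excluded from the
ranking of that repeat and assigned rank n_valid + 1.  A cell's final
score is its rank sum over repeats normalized by the maximum cell
sum; lower is better.

Model selection: greedy pick of k = 4 lowest-score cells with a
minimum Chebyshev index spacing (default a tenth of the longer grid
axis — the "different grid regions" requirement made quantitative),
refit on the full benchmark.  Held-out TPR/FPR are the cell's CV
means; ensemble weights are proportional to the estimated PPV and
normalized to sum 1 (a documented choice; selection by PPV favors
conservative, high-precision models).  A mutation's score is
Σ weight × [model votes +1] ∈ [0, 1].  The trained ensemble, scalers
and grid metadata serialize to a versioned joblib archive.  A
scikit-learn facade (`EnsembleStabilityClassifier`) exposes
fit/predict/decision_function for pipeline composition.

Desk-scale testing uses a 25 × 25 coarse grid (step 2.0, same range
and cell semantics); the full 62,500-cell sweep is constructed but
never fit in the test suite.

## Post-processing

The pocket exclusion set contains generic positions contacting a
ligand in strictly more than `threshold` (default 5) distinct class-A
structures; the packaged default contact table is a curated stand-in
covering the commonly reported orthosteric-pocket positions
(3.32–3.37, 5.42–5.46, 6.48–6.55, 7.35–7.43) and is user-overridable.
Candidates at unannotated (loop/terminus) positions are dropped.
Filtering is monotone and idempotent.

Cross-lane rank aggregation is not uniquely determined by the
problem; the implemented heuristic ranks by (number of proposing
lanes, then the best within-lane normalized rank), because
multi-lane agreement is the only cross-lane signal on a common scale.
Double-Cys bridges bypass the single-substitution ML lane and carry
structure-lane scores only.

## Synthetic generators

All generators are pure functions of their spec including the seed,
and write real on-disk formats (aligned FASTA, PDB, TSV) so tests
exercise the production readers.

* `synth_msa`: per-column consensus with controlled conservation;
  planted columns place a rare residue in the target only.
* `synth_bundle`: ideal α-helices built by internal-coordinate (NeRF)
  chain construction (φ = −57°, ψ = −47°, ω = 180°), arranged
  antiparallel on a circle (default 7 helices × 18 residues, radius
  8 Å, seed-random helix phases), full backbone + Cβ, membrane normal
  = z.  The default geometry contains pairs inside both the
  ionic-lock and the disulfide Cβ window.  Smaller test bundles
  (2–3 helices, ~30 residues) keep the energy-filtered proposal runs
  inside a few seconds.
* `synth_benchmark`: standard-normal feature vectors with the
  positive class shifted by `effect` standard deviations along a
  planted direction; default class sizes 79/923 mirror the imbalance
  of real alanine-scan stability panels.

What the fixtures do *not* emulate: real GPCR sequence composition
and phylogenetic correlation between MSA rows, loops/termini in the
structural models, membrane and solvent atoms, and any correlation
between the planted benchmark signal and the real feature physics.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted signal, not predictive accuracy on real
receptors.

## Numerical choices and degenerate inputs

* PPV is undefined at TPR = FPR = 0 (signalled, cell excluded).
* Rank ties share the average rank; a repeat's valid ranks sum to
  n(n+1)/2.
* `stability_accept` is a strict inequality: an identity mutation or
  an exact tie is rejected.
* Repacking of a residue without rotamers (Gly/Ala) silently keeps it
  rigid; an empty site set returns the model unchanged.
* Structure files with residues missing a Cβ fall back to the virtual
  Cβ only when the backbone is complete; otherwise a structure
  integrity error names the residue.
* All randomness flows through `numpy.random.default_rng(seed)`;
  repeat splits draw child seeds below 2³¹.

## Known limitations

* The energy surrogate is a coarse, documented stand-in: it ranks
  wt/mut pairs under its own physics and does not reproduce any
  published force-field energies.  Its verdicts on disulfides in
  densely packed models are conservative.
* The reverse-mutation examples in benchmark assembly reuse the
  forward-mutated structure rather than a separately refined mutant
  model.
* Cross-lane ranking is a heuristic; lanes score on incommensurable
  scales and only co-proposal is used as a shared signal.
* Backbone flexibility, explicit membrane/solvent, homology modeling
  and any prediction of expression yield or melting temperature are
  out of scope.
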