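# gpcrstab

Prediction of thermostabilizing point mutations for G protein-coupled
receptors (GPCRs).

GPCRs are seven-transmembrane-helix (7TM) proteins whose conformational
flexibility and low melting temperature make structural and biochemical
work difficult; most solved GPCR structures required engineered
constructs carrying stabilizing point mutations found by expensive
alanine scanning.  `gpcrstab` composes a ranked candidate list of such
mutations for a target receptor from four complementary prediction
lanes:

1. **Knowledge lane** — a short, user-extendable table of transferable
   class-A mutations at conserved sites (sodium pocket D^2.50^N,
   S^3.39^A, D^7.49^N; the X^3.41^W TM3/4/5 interface rule; P-I-F and
   DRY microswitches; Y^5.58^A; L^6.37^A).  Positions use GPCRdb
   (Ballesteros–Weinstein) generic numbering `tm.offset`; an applicable
   rule scores 1.0.
2. **Sequence lane** — per-position conservation-deviation scores over
   up to five multiple sequence alignments at increasing evolutionary
   depth.  For column *k* and residue *aa*:

   `score_k(aa) = (C_k^max − C_k^aa)/N_MSA − C_k^aa/C_k^max`

   with `N_MSA` sequences, modal count `C_k^max` and target-residue
   count `C_k^aa`.  The score lies in [−1, 1]; a rare residue in an
   otherwise super-conserved column approaches 1, and the candidate
   mutation restores the conserved residue.  Non-conserved wild-type
   glycines are doubled (Gly destabilizes TM helices).  Per-MSA
   matrices are averaged cell-wise into a net matrix.
3. **Structure lane** — geometric screens over a user-supplied 3D
   model for engineerable ionic locks (sequence separation ≥ 5,
   Cβ–Cβ ∈ [7, 10] Å, inward- and mutually-facing side chains; charged
   pairs E-K/E-R/D-K/D-R in both orders) and disulfide bridges
   (Cβ–Cβ ∈ [3.4, 4.7] Å, idealized χ3 within ±30° of ±87°).
   Survivors are side-chain repacked (seeded discrete-rotamer
   Metropolis search) and kept only if the packaged empirical energy
   surrogate predicts `E_folded(mut) − E_unfolded(mut) <
   E_folded(wt) − E_unfolded(wt)`.
4. **ML lane** — an RBF-SVM ensemble over 40-component feature vectors
   (sequence, structure and energy blocks for the wild-type and the
   repacked mutant residue).  The (C, γ) plane is scanned on a
   250 × 250 grid; repeated stratified 65/35 splits are scored by
   positive predictive value `PPV = TPR/(TPR + FPR)`, cells ranked per
   repeat, and four models from distinct grid regions refit on the
   full benchmark with PPV-proportional weights.  A mutation's score
   is the weighted positive vote.

Post-processing removes candidates at ligand-binding-pocket generic
positions (seen in more than five class-A structures; sodium-pocket
rules are flagged but kept) and at loop/terminus positions, then
merges the lanes into one ranked report with concatenated provenance.

A fixtures module generates every input synthetically (toy MSAs,
idealized 7TM bundles, planted-signal benchmarks), so the package
builds and tests fully offline.

## Worked example

The packaged miniature receptor (a serotonin-receptor-like annotation
with D at 2.50, M at 3.41, and a rare Cys at the otherwise
Asn-conserved 7.45 column) runs through the knowledge and sequence
lanes:

```python
from gpcrstab import mini_receptor, run_pipeline
from gpcrstab.postprocess import report_frame

annotation, msas, target_id = mini_receptor()
result = run_pipeline(annotation, msas=msas, target_id=target_id, top_k=10)
print(report_frame(result.report).to_string(index=False))
```

```
 rank    mutation         provenance  final_score         flags  score_knowledge  score_sequence
    1 M143^3.41^W knowledge+sequence     2.500000                            1.0        0.762500
    2 C360^7.45^N           sequence     2.000000                            NaN        0.949718
    3  D99^2.50^N          knowledge     2.000000 sodium_pocket              1.0             NaN
    4 S141^3.39^A          knowledge     1.666667 sodium_pocket              1.0             NaN
```

Reading: `M143^3.41^W` is proposed both by the knowledge rule X^3.41^W
and by the sequence lane (the 3.41 column is Trp-conserved), so it
ranks first with both provenances; `C360^7.45^N` is the sequence
lane's top single-lane candidate (deviation score 0.95, close to the
theoretical maximum) — it restores the conserved sodium-pocket
asparagine at 7.45.  Sodium-pocket knowledge rules are flagged because
they can trade receptor signaling for stability.

The same pipeline is exposed on the command line
(`gpcrstab knowledge | sequence | structure | ml-train | ml-score |
run-all | synth`), e.g.:

```bash
gpcrstab synth bundle --seed 1 --out bundle.pdb --annotation-out ann.tsv
gpcrstab structure --annotation ann.tsv --model bundle.pdb --seed 1
```

Predicted melting-temperature gains, hit rates and other laboratory
measurements are outside the scope of this package: it ranks
candidates, it does not predict Tm values.

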