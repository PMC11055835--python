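# phlipkit

Design and characterization analytics for pHLIP-like peptides — the
computational workflow behind a pH-triggered tumor-targeting radiotracer
study.

pH (low) insertion peptides (pHLIPs) are ~25–36-residue peptides that are
unstructured at neutral pH but protonate their Asp/Glu side chains in an
acidic tumor microenvironment (pH ≈ 6.0–6.5), fold into an α-helix, and
insert their C-terminal segment into the cell membrane. A radiolabeled
pHLIP therefore accumulates in acidic tumors such as triple-negative
breast cancer. `phlipkit` covers the desk side of such a study:

* **Consensus design** (`phlipkit.design`): given an aligned family of
  membrane-insertion segments, tabulate the position frequency matrix,
  take the most frequent residue at each position, and apply a
  substitution policy (by default every consensus Glu becomes Asp, since
  Glu hydrogen-bonds to membrane cholesterol and slows clearance of
  unbound tracer).
* **Physicochemical descriptors** (`phlipkit.seqcore`): net side-chain
  charge; GRAVY, the grand average of Kyte–Doolittle hydropathy
  `(1/L)·Σᵢ KD(sᵢ)`; the Guruprasad instability index
  `(10/L)·Σᵢ DIWV(sᵢ, sᵢ₊₁)` over consecutive dipeptides; average mass
  with C-terminal amide and N-terminal chelator-adduct handling; and
  ProtScale-style sliding-window hydropathy profiles.
* **Helix analytics** (`phlipkit.helix`): helical-wheel projection at
  100°/residue, mean Fauchère–Pliska hydrophobicity of the C-terminal
  18-residue insertion window, and the Eisenberg hydrophobic moment
  `μH = (1/N)·√[(Σ Hₖ sin kδ)² + (Σ Hₖ cos kδ)²]`.
* **Radiotracer quantification** (`phlipkit.radiometrics`): Ga-68 decay
  correction `counts · 2^(t/T½)` (T½ = 67.71 min), percent injected dose
  per gram of tissue (%ID/g), per-organ mean ± SD cohort summaries,
  Levene's test and one-way ANOVA, serum protein-bound fractions, and
  radiochemical yield/purity arithmetic.
* **Synthetic data** (`phlipkit.synthsim`): seeded generators for aligned
  peptide families with controlled per-position conservation, and for raw
  gamma-counter biodistribution datasets whose analyzed %ID/g values are
  log-normal around specified organ/timepoint means.

## Worked example

The five peptides of the study ship as `phlipkit.STUDY_PEPTIDES`
(YJL-4, the designed tracer; kVar7, its pH-insensitive control; and the
tumor-targeting pHLIP variants Var0-WT, Var3, Var7). Profiling them:

```sh
python -c "
from phlipkit import STUDY_PEPTIDES, io
io.write_peptides(STUDY_PEPTIDES.values(), 'study.fasta')"
phlipkit profile study.fasta
```

prints

```
id,sequence,length,net_charge,instability_index,gravy,average_mass,insertion_hydrophobicity,insertion_moment
YJL-4,ACDDQNPWARYADLLFPTDTLLLDL,25,-4,31.32,-0.092,2879.2,0.763,0.358
kVar7,ACEEQNPWARYLKWLFPTKTLLLKL,25,2,39.04,-0.248,3061.64,0.834,0.399
Var0-WT,ACEQNPIYWARYADWLFTTPLLLLDLALLVDADEGT,36,-5,16.08,0.3,4111.63,0.668,0.07
Var3,ACDDQNPWRAYLDLLFPTDTLLLDLLW,27,-4,41.24,0.096,3221.63,0.991,0.245
Var7,ACEEQNPWARYLEWLFPTETLLLEL,25,-4,50.92,-0.2,3065.45,0.893,0.373
```

Reading the YJL-4 row: an instability index of 31.32 (< 40) classifies it
as stable in vitro and more stable than Var3 (41.24) and Var7 (50.92); a
GRAVY of −0.092 makes it mildly hydrophilic overall, hence easier to
handle in aqueous solution than Var0-WT (0.3) or Var3 (0.096); yet its
C-terminal 18-mer insertion window has a strongly hydrophobic
Fauchère–Pliska mean of 0.763, the amphipathic asymmetry that drives
membrane insertion. `average_mass` is the bare amidated peptide — add the
chelator's mass via `n_mod_mass` if the N-terminus carries one.

The same workflow from the library:

```python
from phlipkit import STUDY_PEPTIDES, describe, insertion_region, hydropathy_profile

d = describe(STUDY_PEPTIDES["YJL-4"])
print(d.rounded()["instability_index"])   # 31.32
print(insertion_region(STUDY_PEPTIDES["YJL-4"]).residues)  # WARYADLLFPTDTLLLDL
```

Other subcommands: `phlipkit design` (consensus from a family FASTA),
`phlipkit wheel` / `phlipkit scan` (helical-wheel CSV and ranked window
scans), `phlipkit simulate-family` / `phlipkit simulate-biodist`
(synthetic inputs) and `phlipkit biodist` (%ID/g, cohort summaries and
ANOVA from raw gamma-counter CSVs).

A note on hydrophobic moments: `insertion_moment` uses the Eisenberg
mean-vector convention, which is cross-checked against an independent
trigonometric oracle in the test suite. Published moment values for these
peptides were computed with a web tool whose exact window and
normalization are not recoverable, so they are not reproduced verbatim;
see `docs/methods.md`.

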