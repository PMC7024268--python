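# pepdisrupt

Design and characterization of linear-peptide disruptors of protein–protein
interfaces, built around the Hsp90–Cdc37 chaperone/co-chaperone system.

Hsp90 matures its kinase clients (e.g. Cdk4) only with the help of the
co-chaperone Cdc37, which grips the chaperone through two sequence stretches
of its N-terminal region — Y4–D15 and L119–N130 — that are far apart in
sequence but adjacent in the folded complex. A peptide that mimics this
interaction surface can compete with Cdc37 for Hsp90 and selectively shut
down kinase maturation without touching the ATPase site. `pepdisrupt`
implements the computational side of that design campaign as a reusable,
tested pipeline:

1. **Hydrogen-bond persistence** — for a conformational ensemble (multi-model
   PDB), the percentage of frames in which each interfacial donor/acceptor
   pair satisfies a heavy-atom geometric criterion (d(D···A) ≤ 3.5 Å,
   ∠(antecedent–D–A) ≥ 120°).
2. **Interface excision** — ligand-side contact residues (heavy-atom cutoff
   5 Å), contiguous stretches, and sliding-window peptide candidates that
   keep their parent coordinates as an anchor pose; plus joining two
   stretches into one design and phosphomimetic substitution
   (S → D/E at a phosphosite such as Cdc37 S13).
3. **Binding-funnel analysis** — a declared coarse-grained energy
   E = w_hb·N_hb + w_ct·Σc(i,j) + w_cl·N_clash (model units), RRT
   (rapidly exploring random tree) sampling of alternative conformations
   around the anchor, and the funnel steepness: the OLS slope of
   ΔE against Cα-RMSD. For 10–15-mers, slope > 5 calls a binder.
4. **Conservation-guided mutation search** — beam search over point
   substitutions (BLOSUM62-guided allowed sets, prior proportional to
   per-column conservation of an MSA) improving energy and steepness.
5. **Peptide chemistry** — average/monoisotopic masses with C-terminal
   amidation and phosphomodifications, and the ESI positive-mode charge
   series m/z = (M + n·1.00728)/n.

A synthetic-data module generates toy groove complexes, ensembles with
*programmed* per-bond occupancies, linear funnels and alignments with known
conservation, so every stage is validated against ground truth without any
structure download or trajectory.

## Worked example

```python
import pepdisrupt as pd
from pepdisrupt.synthetic import groove_hbond_specs

# toy receptor groove holding the L119-N130 stretch sequence
complex_ = pd.make_toy_complex(14, "LSKDGFSKSMVN", seed=1)
ensemble = pd.make_ensemble(complex_, 500, groove_hbond_specs(complex_, 0.9), seed=0)

records = pd.persistence(ensemble, {"R"}, {"P"}, min_percent=40.0)
for r in records[:3]:
    print(f"  {r.pair_label}  {r.percent:.2f}")

spans = pd.contiguous_stretches(pd.interface_residues(complex_, ["R"], "P"))
best = pd.rank_candidates(pd.excise_windows(
    complex_, "P", spans, (10, 12), receptor_chains=["R"]))[0]
print(f"best window: {best.sequence}  E = {best.binding_energy:.2f} model units")

samples = pd.rrt_explore(complex_, best.anchor,
                         pd.RRTParams(max_nodes=300, seed=7),
                         receptor_chains=["R"])
stats = pd.funnel_steepness(samples)
print(f"funnel slope = {stats.slope:.2f}; call: {pd.is_binder(stats, len(best)).value}")

report = pd.mass_report(best.sequence, c_term_amide=True)
print(f"average mass = {report.average:.2f} Da, [M+H]+ = {report.esi_monoisotopic[1]:.2f}")
```

prints

```
  VAL11@N:VAL11@O  92.80
  ALA5@N:GLY5@O  90.80
  GLU6@N:PHE6@O  90.60
best window: LSKDGFSKSMVN  E = -28.60 model units
funnel slope = 9.56; call: binder
average mass = 1311.51 Da, [M+H]+ = 1311.67
```

The persistence lines recover the 90 % occupancy programmed into the
synthetic ensemble; the full-stretch 12-mer wins the excision scan (it makes
the most groove hydrogen bonds); its funnel rises steeply away from the
anchor pose, so the slope rule calls it a binder; and the amidated peptide's
average mass and [M+H]+ ion match what a mass spectrometrist would expect
for this sequence.

The same stages are exposed on the command line:

```sh
ppm hbonds ensemble.pdb --receptor R --ligand P --min-percent 40
ppm excise complex.pdb --receptor R --ligand P --lengths 10:15
ppm funnel complex.pdb --receptor R --ligand P --span 1:12 --nodes 500 --seed 7
ppm chem --seq LSKDGFSKSMVN --amide
ppm run config.toml        # full pipeline from a flat TOML config
```

## Documentation

`docs/methods.md` describes the model assumptions, the default parameters
and why, what the synthetic generators emulate (and what they deliberately
do not), and the known limitations of the coarse-grained energy scale.
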