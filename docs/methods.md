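# Methods

## Scope and model overview

`pepdisrupt` turns the design workflow for peptide disruptors of the
Hsp90–Cdc37 interface into a reusable pipeline: persistence mapping of the
interfacial hydrogen-bond network over a conformational ensemble, excision
of linear interface peptides with an anchor pose, randomized exploration of
the binding funnel, conservation-guided mutation search, and synthesis-ready
mass characterization. Everything runs at desk scale on a single CPU; the
molecular-dynamics machinery that produces real ensembles (explicit solvent,
thermostats, µs trajectories) is intentionally out of scope and replaced by
a synthetic-ensemble generator with programmed ground truth.

## Hydrogen-bond model

Input structures derive from cryo-EM and carry no hydrogens, so bonding is
decided purely from heavy atoms:

* donor–acceptor distance ≤ **3.5 Å** (configurable),
* antecedent–donor–acceptor angle ≥ **120°** (configurable).

Donor/acceptor typing covers backbone N (antecedent Cα) and O plus the
standard side-chain sites (S/T/Y hydroxyls in both roles; K/R/N/Q/H/W
nitrogen donors; D/E/N/Q oxygen acceptors; H ring nitrogens in both roles;
phosphoserine/-threonine/-tyrosine phosphate oxygens as acceptors, with
SEP/TPO/PTR mapped onto phospho-S/T/Y at parse time). Persistence over an
ensemble is the percentage of frames in which a given atom-level pair is
bonded; a residue-level view takes the maximum over the atom pairs of a
residue pair. Frames are weighted equally. Residue numbering is always the
author (PDB) numbering and is reported as-is, even where deposited numbering
is internally inconsistent.

## Interface excision and design

A ligand residue is interfacial when any heavy atom lies within **5.0 Å**
(configurable) of a receptor heavy atom. Contiguous stretches are maximal
runs of consecutive residue numbers (gap tolerance 0 by default). Candidate
peptides are all windows of the requested lengths (default 10–15, matching
the length range for which the funnel-slope rule is calibrated) inside each
stretch; each keeps its parent coordinates as the anchor pose and its
model-energy score. Ranking is by energy ascending with lexicographic
sequence tie-break, so runs are deterministic.

Two stretches that are adjacent in space can be joined into one design; the
join is `extension + stretchA + stretchB` with the N-terminal extension an
explicit parameter rather than a hard-coded rule, because the choice of
extension is a design decision, not a derivable fact. A position map from
source residue numbers to peptide indices is carried along so a phosphosite
can be addressed by its author number; phosphomimetic substitution replaces
a phosphorylatable S/T/Y by S (identity), D or E.

## Energy model and binding funnel

The original interface-crawling tool's energy function is unpublished, so
this package declares its own three-term coarse-grained model and labels its
outputs "model units":

```
E = w_hbond · N_hbond + w_contact · Σ c(i,j) + w_clash · N_clash
```

with defaults w_hbond = −2, w_contact = −0.5, w_clash = +10. `c(i,j)` is a
hydrophobicity-compatibility factor in [0, 1], the product of the two
residues' Kyte–Doolittle hydropathies rescaled to [0, 1], summed over
receptor–peptide residue pairs with any heavy-atom pair within 6.5 Å;
clashes are heavy-atom pairs under 2.5 Å. Absolute energies are **not**
comparable to published energy scales (−20.37 / −47.28 in the original
tool's units are therefore not reproduction targets); what transfers is the
funnel-slope criterion, which is a threshold on a geometric trend rather
than on an absolute energy.

Alternative conformations are sampled with an RRT: a random goal pose is
drawn inside the exploration ball (rigid shifts of the anchor up to
`rmsd_max`, default 3 Å), the tree node nearest the goal (Cα-RMSD metric) is
extended by one bounded move — translation toward the goal (≤ 0.5 Å),
rigid-body rotation about the centroid (≤ 5°), or a backbone-dihedral twist
about a Cα–C axis (≤ 10°) — and the node is kept if it stays inside the
ball and, when clash rejection is on, clash-free. Defaults: 500 nodes.
Side chains are Cβ pseudo-atoms that ride the backbone; there is no
repacking. RMSD is Cα-only against the anchor without re-superposition,
because the funnel must measure departure from the bound pose in the fixed
receptor frame.

Funnel steepness is the ordinary-least-squares slope of
(E − E_anchor) against RMSD over a window (default the full explored range),
with E_anchor taken from the minimum-RMSD sample. OLS over the full window
is this package's declared estimator; binning or robust alternatives were
considered and rejected as additional unforced choices. The binder call is
**slope > 5** for peptides of length 10–15; outside that length range the
call is a distinct "not calibrated" state rather than a yes/no.

## Mutation search

Conservation is, by default, the frequency of the reference residue in each
alignment column (the simplest estimator that needs no background model);
an entropy-based alternative is available behind a flag. The search is a
beam over mutation sets of size ≤ `max_mutations`: each depth expands all
single substitutions from BLOSUM62-guided allowed sets (top 5 alternatives
of the wild type by default, overridable), prunes to `beam_width` states by
energy improvement, then re-evaluates funnel steepness for survivors only
(a short 100-node RRT per survivor, seeded deterministically per variant).
The objective is

```
(E_input − E_variant) + λ · (slope_variant − slope_input),    λ = 1 by default
```

multiplied by the product of the conservation scores of the mutated
positions — the prior is proportional to conservation, so a position with
score 0 is never mutated and the search degenerates gracefully to "no
proposal" on a fully unconserved profile. The returned best candidate is
never worse than the input; with a beam at least as wide as the full
single-mutant space the search is exhaustive, which is verified against a
brute-force enumeration in the test suite. The exact four-mutation optimized
sequence reported for the real system is not an expected output here: it was
selected under a different (unpublished) energy function, and the package
makes no claim of reproducing it.

## Peptide chemistry

Masses are computed at the elemental-composition level (pyteomics): the
C-terminal amide is the OH → NH₂ substitution (−0.98402 Da monoisotopic,
−0.984 average), a phosphosite adds HPO₃ (+79.96633 / ≈ +79.98 Da), and the
ESI positive-mode series is m/z = (M + n·1.00728)/n for n = 1–4. Reports
carry both the average and the monoisotopic value with a charge series for
each, because experimental characterization tables rarely state which
convention a quoted molecular weight uses. For the designed series, the
computed amidated average masses agree with the published characterization
within 0.02 Da for four of the five peptides; the fifth (the glutamate
phosphomimetic 25-mer) is quoted in the source table as 2913.13 although
mass additivity from its sibling peptides requires ≈ 2914.1 — an internal
inconsistency of the printed table (its own 2+ ion is consistent with
≈ 2913.2 monoisotopic, i.e. the quoted value is most plausibly the
monoisotopic mass). The package reports the computed value and does not
"correct" the table.

## Synthetic data: what it does and does not emulate

* `make_toy_complex` builds a β-strand-like groove: peptide and receptor
  strands in idealized extended geometry (N–Cα 1.46 Å, Cα–C 1.52 Å,
  C–N ≈ 1.35 Å, Cα–Cα rise 3.8 Å, side chains as Cβ pseudo-atoms), with one
  receptor-N → peptide-O hydrogen bond (2.8 Å, ≈ 125°) per groove position
  and no interchain heavy-atom pair under 2.2 Å.
* `make_ensemble` programs each requested bond to hold in a
  Binomial(n_frames, p) number of frames by displacing the acceptor along
  the donor→acceptor axis to cutoff + 1 Å in "broken" frames; all atoms not
  involved in a programmed bond get isotropic Gaussian jitter (σ default
  0.05 Å) applied independently, so programmed states cannot be silently
  flipped. Occupancy analysis must then recover p; at 500 frames the
  binomial width makes ±3 percentage points a reasonable recovery check for
  p around 0.9 (and n = 1000 for p near 0.5).
* `make_funnel_samples` draws from an exactly linear funnel plus Gaussian
  noise, so slope estimators can be checked against closed-form OLS
  behaviour.
* `make_msa` programs per-column conservation exactly.

None of these emulate real conformational dynamics, solvation, cooperative
unbinding, or phylogenetic correlation between sequences. Passing tests
therefore demonstrate that the *analysis* is correct against known ground
truth, not that the energy model predicts real binding affinities.

## Determinism and numerical choices

All generators and search procedures are pure functions of (parameters,
seed); the pipeline derives stage seeds from one master seed and re-runs are
byte-identical on all tabular outputs. Alternate-location conformers in PDB
input keep the highest occupancy (ties: first encountered). Degenerate
funnel input (all samples at one RMSD) is an error, not a zero. Candidate
and proposal ties break lexicographically by sequence. Test problem sizes —
14-residue receptor grooves, 500-frame ensembles, 100–500-node RRT runs,
1000-sequence alignments — were chosen so the full suite completes in well
under a minute while keeping binomial/OLS recovery intervals tight.

## Known limitations

* The energy scale is a declared stand-in; only orderings and the
  slope-threshold rule are meaningful, not absolute values.
* Side-chain flexibility is absent (Cβ pseudo-atoms); real funnels of
  long-side-chain residues will be smoother than the model's.
* Hydrogen-bond detection is geometric-only; no energetic or
  orientation-dependent refinement.
* The MSA conservation model treats columns independently and sequences as
  unrelated; real alignments carry phylogenetic structure.
* mmCIF input, crystallographic symmetry and occupancy semantics beyond
  altloc resolution are not supported.
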