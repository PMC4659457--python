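# Methods

## The model of the problem

A type I collagen molecule is a heterotrimer — two α1 chains and one α2 —
whose ~1014-residue triple-helical domain is flanked by short non-helical
telopeptides. In a fibril the molecules pack in a staggered, quasi-crystalline
arrangement (the D-period), which this package represents by a triclinic
periodic cell: every steric question about "a neighbouring molecule" becomes a
minimum-image question about a periodic copy of the one modelled molecule.

Glucosepane formation requires a lysine (or hydroxylysine, which retains the
reactive free amine) and an arginine to be close in space on *different*
chains of the helix. Candidate sites are screened on a single low-energy
conformation by measuring the inter-side-chain separation at three points
(Nζ–Nη, Cε–Nε, Cδ–Cδ); a pair qualifies if any of the three distances is
within the cutoff. Whether a qualifying site is *thermodynamically* plausible
is then decided from simulation energetics: the mean total energy of the
cross-linked system minus that of a matched native reference (unbound
glucose, minus the four waters released by the condensation), averaged over
the equilibrated tail of the production run. An exothermic difference
(ΔH < 0) marks the site favourable.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| distance cutoff | 5.0 (inclusive) | Å | roughly twice the N–N separations inside glucosepane (~2.5 and ~3.7 Å); ties included so boundary pairs are never silently dropped |
| η-nitrogen convention | min(NH1, NH2) | — | the criterion is a proximity screen, so the closer η nitrogen governs feasibility |
| contact threshold | 4.0 | Å | upper end of the 1.5–4.0 Å close-contact range relevant to clash assessment |
| severe threshold | 2.5 | Å | a contact this deep is treated as a hard clash; the site is marked *excluded* rather than dropped, keeping the call auditable |
| image search | shifts in {−1,0,1}³ | — | valid while side chains are much smaller than the cell; a documented precondition |
| analysis window | final 25 ns (of 60 ns) | ns | tail of the production run after energies have converged |
| SEM method | naive (sd/√n); block (k=5) optional | kcal/mol | the naive SEM matches the headline statistic; block averaging is the defensible choice for autocorrelated traces |
| ΔH = 0 tie-break | unfavourable | — | "favourable" means strictly exothermic |
| proximity window | 5 | residues | covers the "two residues down" protease-site case with margin |
| chain offsets | α1 = 167, α2 = 96 for the reference table | residues | derivable from any dual-numbered residue table via `derive_offsets`, which hard-errors on inconsistency |

Protonation rules for the charge census default to standard states at
physiological pH (Lys/Hyl/Arg +1, Asp/Glu −1, His 0, termini ignored) and
are overridable; unknown residue names are a hard error, never silently
neutral.

## Numerical choices

- **Windows are half-open** `[t_start, t_end)` so concatenated windows
  partition frames exactly; `AnalysisWindow.last` extends one frame spacing
  past the final sample so the last frame is included.
- **Cutoff ties**: the inclusive cutoff carries a 1e-9 Å guard so a pair
  constructed to sit exactly at the cutoff is not lost to the last float ulp.
- **Minimum image** is evaluated by direct vectorized enumeration of the 27
  lattice shifts (the same set the contract defines), not by fractional
  rounding, so skewed cells need no special-casing.
- **Steric exclusions**: within the same molecule (zero shift) the site's own
  residues and their covalent sequence neighbours are excluded from the
  contact list; image contacts are kept regardless, because an image is a
  different molecule of the fibril.
- **Convergence** is the earliest window start whose least-squares energy
  slope magnitude falls within tolerance, scanned at every frame via
  closed-form rolling sums. With a window of length L over a drift that stops
  abruptly, the slope criterion is met once roughly 80% of the window is past
  the drift, so detection lands within one window length of the true
  breakpoint.
- ΔH uncertainty combines the two series' SEMs in quadrature, treating the
  traces as independent.

## The synthetic-data generator

The generator's job is geometric and statistical plausibility, not
structural fidelity — building a real collagen model from sequence is out of
scope. It emulates:

- an idealized triple helix with 10/3 symmetry (2.86 Å rise, −103.9° twist
  per residue), 2.6 Å backbone radius, one-residue chain stagger, and a
  repeating Gly-Pro-Hyp sequence with Lys/Hyl/Arg substitutions;
- **planted candidate pairs**: minimal side chains (exactly the criterion
  atoms) placed in closed form so each criterion distance is met exactly;
  the contact centre is pushed radially outside the backbone circle so
  planted side chains do not thread through the helix core;
- **planted clashes**: an extra residue positioned so its amine sits a
  prescribed distance from the site in a prescribed neighbour image;
- a periodic cell sized from the realized coordinates so unplanted atoms
  stay > 8 Å from every image (clashes exist only where planted);
- **energy series** as stationary AR(1) processes around a planted mean.
  Defaults are the study conditions the analysis targets: 60 ns of
  production sampled every 0.01 ns with per-frame sd 35 kcal/mol, giving a
  last-25-ns naive SEM of 35/√2500 ≈ 0.7 kcal/mol per trace. The planted
  mean offset between the cross-linked and native series is the ground-truth
  ΔH; under these conditions planted offsets spanning the reference range
  [−40, +95] kcal/mol are recovered within ±3 SEM in ≥ 99% of runs.

What passing tests on this synthetic data do **not** show: fidelity to real
collagen side-chain rotamers, sequence composition, solvent or force-field
effects, or trajectory-averaged (rather than single-conformer) geometry.
They do show that the search, screen, statistics and bookkeeping are exact
on inputs with known ground truth.

## Design choices where the design was open

- The two α1 copies are distinguished by fixed labels `A1A`/`A1B`; the
  user's chain map decides which file chain is which, since a stable (a)/(b)
  convention is required to report sites unambiguously.
- Structure-file residue numbers are taken verbatim as UniProt numbering;
  helical indices are assigned by per-chain offsets, with out-of-range
  residues flagged telopeptide and excluded from the search.
- Hydroxylysine is accepted under a configurable alias set (`HYL`, `LYZ`)
  because PDB dialects vary.
- Sterically excluded sites enter the summary as their own class. Because
  the reference presentation counts them together with the endothermic
  sites, the summary also reports the combined not-favourable count
  (16 + 2 = 18 for the reference table).
- The packaged ECM domain map is a synthetic fixture: the published
  interaction-domain map is not reproduced, so each named biomolecule gets an
  interval covering the favourable site(s) it reportedly overlaps, and the
  MMP1 interval begins two residues past site 17's lysine so it annotates as
  proximal. The TSV format is open for users to supply a real map.
- Whether "total energy" means potential or potential+kinetic is left to the
  input: the analysis uses whatever the energy column contains, requiring
  only that both series report the same quantity.

## Known limitations

- The steric screen flags severe clashes; it cannot reproduce a qualitative
  human exclusion judgement beyond its thresholds.
- Candidate geometry is evaluated on one static conformation; residence-time
  criteria over a trajectory are out of scope.
- The naive SEM underestimates uncertainty for autocorrelated traces; block
  averaging is provided but k = 5 is a convention, not an optimum.
- Problem sizes in the test suite (helices of 9–30 residues per chain,
  energy traces of 6000 frames, 100–400 randomized oracle trials) were
  chosen to exercise every code path with exact ground truth at desk scale.
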