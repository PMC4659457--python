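# glycolink

Glucosepane is the most abundant advanced glycation end-product (AGE)
cross-link in long-lived proteins: a seven-membered ring formed
non-enzymatically between a lysine (or hydroxylysine) side-chain amine and an
arginine guanidinium. Its accumulation in type I collagen is linked to
age-related stiffening of tendon, bone and dermis, and its position within a
collagen molecule determines which extracellular-matrix (ECM) interactions it
can disrupt. `glycolink` is a pipeline for locating and classifying
*intramolecular* glucosepane cross-link sites in a collagen molecule embedded
in a periodic fibril, for structural bioinformaticians who have a collagen
model (PDB) and per-site molecular-dynamics energy traces.

## What it computes

1. **Candidate search** — the side-chain separation of every inter-chain
   Lys/Hyl–Arg pair inside the triple-helical domain, measured at three
   points: Lys N<sup>ζ</sup>–Arg N<sup>η</sup> (minimum over NH1/NH2),
   Lys C<sup>ε</sup>–Arg N<sup>ε</sup>, Lys C<sup>δ</sup>–Arg C<sup>δ</sup>.
   A pair is a candidate when any of the three distances is ≤ 5 Å
   (inclusive).
2. **Steric screen** — heavy-atom close contacts between a candidate's side
   chains and the rest of the molecule *or any neighbouring periodic image*
   of it, under the minimum-image convention in a triclinic cell
   (shifts in {−1,0,1}³). Contacts ≤ 4 Å are reported; a contact ≤ 2.5 Å
   marks the site **excluded**.
3. **Binding enthalpy** — for each surviving site,
   ΔH = ⟨E<sub>cross-linked</sub>⟩ − ⟨E<sub>native</sub>⟩ over an analysis
   window (default: the final 25 ns), with a standard error of the mean
   (naive, or block-averaged for autocorrelated traces) combined in
   quadrature. ΔH < 0 (exothermic) ⇒ **favourable**; ΔH ≥ 0 ⇒
   **unfavourable**.
4. **Domain annotation** — overlap and proximity of each site against a
   named interval map of ECM binding domains (heparin, decorin, integrins,
   MMP1, interleukin-2, ...) in triple-helical coordinates.

Residues carry dual numbering (UniProt precursor vs triple-helical index);
the per-chain offsets interconvert them, and a packaged 24-site reference
table exercises the whole numbering and classification machinery.

A synthetic-data generator builds idealized triple helices (10/3 symmetry,
2.86 Å rise) with planted candidate pairs, planted periodic clashes, and
AR(1) energy series with planted mean offsets, so every stage is testable
without external data.

## Worked example

```sh
cat > helix.yaml <<'EOF'
n_residues: 24
rise_per_residue: 8.0
backbone_radius: 14.0
plants:
  - kind: candidate_pair
    lys_slot: [A1A, 5]
    arg_slot: [A2, 5]
    distances: [4.2, 6.0, 7.0]
EOF
glycolink simulate structure --spec helix.yaml --out model.pdb
printf 'mean: -1010.0\nseed: 5\n' > series.yaml
glycolink simulate energies --spec series.yaml --out site01.dat
python -c "from glycolink.synthetic import SeriesSpec, generate_energy_series;
generate_energy_series(SeriesSpec(mean=-1000.0, seed=4)).to_table('native.dat')"

glycolink find-sites  --structure model.pdb --out sites.csv
glycolink energetics  --native native.dat --crosslinked site01.dat --site-id 1 --out enthalpy.csv
```

which prints

```
1 candidate site(s) -> sites.csv
site   dH (kcal/mol)     SEM  classification
   1         -10.411   0.994  favourable
```

The planted pair (closest criterion distance 4.2 Å) is the one candidate; the
cross-linked trace was generated 10 kcal/mol below the native reference, and
the estimated enthalpy change −10.411 ± 0.994 kcal/mol recovers that planted
offset within one standard error and classifies the site favourable
(exothermic). `glycolink run --config run.yaml` chains all stages and also
writes `contacts.csv`, `annotated.csv`, a site-distribution track
(`distribution.tsv`) and `summary.json`.

The packaged ECM domain map (`ecm_domains_synthetic.tsv`) is a synthetic
fixture encoding qualitative containment only; supply a real interval map in
the same TSV format for production use.

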