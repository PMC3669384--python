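# metabodiv

Metabolomic-microdiversity analysis for co-occurring bacterial strains, built
for the kind of study in which dozens of isolates of one species (e.g.
*Salinibacter ruber* strains from solar-saltern crystallizer ponds) are
profiled by direct-infusion ultra-high-resolution mass spectrometry
(FT-ICR-MS) in several cellular fractions, and the question is how much
metabolic diversity hides inside a phylogenetically homogeneous species.

The package takes per-sample peak lists — `(m/z, intensity, S/N)` triples —
through the complete analysis:

1. **I/O and alignment** — read TSV peak lists (S/N ≥ 1, window 150–2000
   m/z), align peaks across samples into a feature × sample intensity matrix
   by single-linkage binning at a ppm tolerance (default 1 ppm).
2. **Formula assignment** — convert [M+H]⁺ ions to neutral masses,
   exhaustively enumerate CHNOS formulas within 0.5 ppm, validate with the
   nitrogen rule, O/C ≤ 1, RDBE ∈ [0, 40] and element bounds (C ≤ 100,
   O ≤ 80, N ≤ 5, S ≤ 1), and strip ¹³C isotopologue satellites
   (Δm = 1.0033548 Da, intensity ratio ≈ 0.0107 · C).
3. **Networks** — a mass-difference network (edges = exact biochemical
   transformation masses at 0.1 ppm, nodes = formulas assigned at < 0.5 ppm)
   and a sample-correlation network (edges = Pearson r > 0.90).
4. **Discriminative metabolites** — OPLS-DA on log₁₀ intensities
   (centering + Pareto scaling) with three intersected selection rules:
   VIP ≥ 1, where VIP_j = √(p · Σ_a w²_ja SSY_a / Σ_a SSY_a); the S-plot
   rule (both |cov(t₁, x_j)| and |corr(t₁, x_j)|, scaled to max = 100 %,
   above 50 %); and a two-sided Wilcoxon rank-sum test at raw p < 0.05
   (Benjamini–Hochberg q-values reported alongside).
5. **Metabotype OTUs** — Ward clustering of strain profiles (heights = ESS
   increase), cut at a percentage of the maximal merge distance to define
   *m*-OTUs, with Shannon–Weiner index H = −Σ p_i ln p_i, Good's coverage
   C = 1 − n₁/N, and analytical (hypergeometric) rarefaction
   E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)].
6. **Annotation & reports** — match formulas to a local
   formula → metabolite/pathway/class table and emit discrimination
   summaries in the two published percentage styles.
7. **Fingerprints** — Dice/UPGMA dendrograms for PFGE band patterns and
   matched-peak/single-linkage dendrograms for MALDI-TOF profiles.
8. **Synthetic data** — a seeded generator producing peak lists with known
   ground truth (core + group-elevated accessory formulas, sub-ppm mass
   noise, log-normal intensities, noise peaks, optional ¹³C satellites), so
   every stage is testable without instrument data.

## Worked example

```python
import metabodiv as md

# a synthetic study: 5742 formulas, 274 old-elevated + 136 new-elevated,
# 20 old + 20 new strains, realistic noise
truth = md.generate_truth(md.TruthConfig(), seed=21)
peaklists, manifest = md.simulate_peaklists(
    truth, md.NoiseModel(), {"old": 20, "new": 20}, seed=22)

matrix = md.align_peaklists(peaklists, tol_ppm=1.0)
labels = matrix.sample_meta["age_class"].to_numpy()
result = md.discriminative_features(matrix, labels)
print(len(result["selected"]), "discriminative features")
rep = md.build_report("SP (SN2)", "old-vs-new",
                      total_metabolome=truth.n_formulas,
                      discriminative=len(result["selected"]),
                      annotable=0, with_pathway=0)
print(rep.discriminative_pct)
```

prints

```
407 discriminative features
7%
```

i.e. the three intersected rules select 407 features — almost exactly the
410 planted group-elevated formulas (precision 1.00, recall 0.993 against
the ground truth) — and the integer-style report renders them as 7 % of the
5742-feature metabolome.

Formula assignment in one line:

```python
>>> [c.formula for c in md.enumerate_formulas(174.111676)]
['C6H14N4O2']          # arginine, |error| < 0.01 ppm
```

A command-line interface mirrors the stages
(`metabodiv simulate | align | assign | network | discriminate | motu |
report | fingerprint`); run `metabodiv --help`.

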