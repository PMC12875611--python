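# limbsym

Quantifying dorsoventral mirror symmetry in limb cross-sections.

Regenerated axolotl limbs can form mirror-duplicated ("double-dorsal" or
"double-ventral") anatomies that are hard to recognise from individual
landmarks because their morphology is highly variable. `limbsym` turns the
question "is this limb internally symmetric about its dorsoventral
midline?" into a number, using the workflow a histology lab would apply to
trichrome-stained transverse sections:

1. **Per-sample trainable pixel classification.** Staining intensity varies
   slide to slide, so each section gets its own classifier: sparse
   scribbles for five tissue classes — background (1), cartilage (2),
   muscle (3), other connective tissue (4), epidermis (5) — train a seeded
   random forest on a multi-scale feature stack (raw color plus Gaussian,
   gradient-magnitude and Laplacian features at σ = 1, 2, 4 px per
   channel), which then labels every pixel.
2. **Mirror-symmetry scoring.** The midpoint of the user-placed dorsal and
   ventral end points defines the axis; the section is rotated so the axis
   is vertical, a window of 400 μm width is cut (external curvature would
   otherwise confound the measure), and the ventral half is flipped onto
   the dorsal half. For each class *c*,

   score<sub>c</sub> = matching<sub>c</sub> / total<sub>c</sub>,

   where matching<sub>c</sub> counts pixels assigned to *c* on **both**
   halves and total<sub>c</sub> counts pixels assigned to *c* on **either**
   half — a per-class Jaccard index of the two mirror halves. A "combined"
   score pools counts over all classes. A perfect mirror scores exactly
   1.0; an intact (asymmetric) limb scores lower.
3. **Group statistics.** Each experimental group is compared to the
   intact-limb reference with two-tailed Welch's t-tests; wound-assay
   outcome tables (regress / bump / limb counts per condition) become
   percentages, with Fisher's exact test for 2×2 contrasts.

Because the original slide images are not deposited, the package ships a
first-class synthetic-section generator: mirror-symmetric blob sections
with an epidermis ring, cartilage and muscle elements, a tunable
`asymmetry` knob in [0, 1] (0 = exact mirror, 1 = independent dorsal and
ventral layouts), and a trichrome-like stain renderer with per-sample
intensity multipliers. Every pipeline stage is tested end-to-end on it.

## Worked example

Generate two cohorts of 12 sections — perfectly mirror-symmetric
(`asymmetry = 0`, emulating a duplicated limb) versus strongly asymmetric
(`asymmetry = 0.8`, emulating an intact limb) — classify each render with
its own per-sample forest, score one 400 μm window per section, and
compare the groups:

```python
import limbsym as ls

cohort = ls.make_cohort(
    ls.SectionSpec(height_px=256, width_px=256),
    group_asymmetries=[0.0, 0.8], n_per_group=12, seed=1,
)
scores = ls.run_cohort_symmetry(cohort, use_classifier=True, seed=1)
print(scores.groupby("group")["combined"].agg(["mean", "sem", "count"]).round(4))

sym = scores.loc[scores.group == "asym0", "combined"]
asym = scores.loc[scores.group == "asym0.8", "combined"]
res = ls.welch_t(sym, asym)
print(f"Welch t = {res.statistic:.2f}, df = {res.df:.1f}, p = {res.p_two_sided:.2e}")
```

prints

```
           mean     sem  count
group
asym0    0.9993  0.0002     12
asym0.8  0.6141  0.0374     12
Welch t = 10.31, df = 11.0, p = 5.43e-07
```

The symmetric group's combined score sits at ~1 (the 0.07 % shortfall is
pixel-classification error, not geometry), the asymmetric group drops to
~0.61, and the groups separate decisively. Outcome-count tables work the
same way from Python or the CLI:

```python
rates = ls.outcome_rates(ls.load_packaged_outcomes())
print(rates.loc[rates.condition.isin(["DorBL", "DorBL + V"]),
                ["condition", "N", "limb_pct_display"]].to_string(index=False))
```

```
condition  N limb_pct_display
    DorBL 12              8.3
DorBL + V 14             50.0
```

i.e. dorsal-only wounds form limbs in 8.3 % of animals, rising to 50 %
when ventral skin is grafted in.

A `limbsym` console script exposes each stage
(`generate` / `train` / `classify` / `score` / `compare` / `outcomes`);
every command is seeded and writes a JSON run manifest, so full pipelines
re-run byte-identically.

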