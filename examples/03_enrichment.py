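"""Class/pathway overrepresentation of a screen's significant metabolites.

Re-runs the planted-LPC screen and asks which annotation terms are
overrepresented among the significant metabolites in muscle.
"""

from metmap import diffstats, enrich, preprocess, synthdata

cohort = synthdata.generate_cohort(synthdata.CohortSpec(seed=2))
annotation = synthdata.generate_annotation(n_gc=60, n_lc=60, seed=2)
effects = synthdata.EffectSpec.from_tuples(
    [("LPC", "muscle", "T2D_vs_nonDM", -1.5)])
data = synthdata.generate_intensities(cohort, annotation, effects, seed=2,
                                      tissues=("muscle",))
scaled = preprocess.preprocess_tissue(
    data.intensity_tables[("muscle", "GC-MS")],
    data.intensity_tables[("muscle", "LC-MS")])
diff = diffstats.differential_screen({"muscle": scaled}, data.samples,
                                     n_perms=20_000, seed=2)

enriched = enrich.enrich_all(diff, annotation)
classes = enriched[enriched.term_type == "class"].head(5)
print(classes[["term", "tissue", "k", "K", "n", "N", "p", "fdr_p"]]
      .to_string(index=False))
print("\nk of K term members among n significant (background N); the "
      "hypergeometric upper-tail p puts the planted LPC class on top.")
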