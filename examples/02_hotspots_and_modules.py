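"""Classify pQTL, call trans-hotspots, build co-expression modules.

Reproduces the analysis chain behind a trans-hotspot landscape: every
feature is scanned, associations are split into cis (within 1 Mb of the gene,
p<1e-5) and trans (elsewhere, p<1e-6), hotspots are windows collecting the
trans peaks of many features, and robust-correlation modules are matched to
hotspots by member overlap with a hypergeometric enrichment p.
"""

from pqtlmap import architecture, assoc, comodule, enrich, simdata

panel = simdata.simulate_panel(seed=2)
abundance, annotation, truth = simdata.plant_architecture(panel, seed=2)

K = assoc.compute_kinship(panel)
records = assoc.scan_features(abundance, panel, K)
classified = architecture.classify_pqtl(records, annotation)
peaks = architecture.feature_peaks(classified)
print(
    f"{(peaks['qtl_class'] == 'cis').sum()} cis-pQTL and "
    f"{(peaks['qtl_class'] == 'trans').sum()} trans-pQTL peaks"
)

hotspots = architecture.detect_hotspots(classified)
for h in hotspots:
    print(f"hotspot chr{h.chrom} peak {h.peak_marker_id}: {h.n_members} member proteins")

modules = comodule.build_modules(abundance)
universe = list(abundance.index)
for m in modules:
    best = max(hotspots, key=lambda h: len(set(m.members) & set(h.member_features)))
    frac, p = comodule.module_hotspot_overlap(m.members, best.member_features, universe)
    print(
        f"module {m.label} ({len(m.members)} members, VE={m.variance_explained:.2f}) "
        f"overlaps chr{best.chrom} hotspot {frac:.0%} (p={p:.1e})"
    )

# category enrichment of the largest hotspot's members
cats = annotation.groupby("category").groups
cats = {k: list(v) for k, v in cats.items() if k != "unassigned"}
res = enrich.enrich_table(set(hotspots[0].member_features), cats, set(universe))
top = res[0]
print(
    f"top enrichment of the chr{hotspots[0].chrom} hotspot: {top.category} "
    f"(k={top.k}/{top.K}, p={top.p:.1e}, q={top.q:.1e})"
)
print("high overlap/enrichment means the hotspot and the module capture the same regulon.")
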