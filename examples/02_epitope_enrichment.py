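"""Affinity selection against a planted epitope, enrichment and hot spots.

Plants a two-stretch epitope (antigen-local 140-154 and 248-254) whose
joint coverage is required for binding, runs two rounds of selection,
ranks the enriched fragments and calls enrichment-factor jump boundaries.
"""

from phagemap import (LibraryCounts, call_hotspots, call_significant,
                      candidate_required_region, classify_library,
                      convert_span, enrichment_factor, rank_fragments,
                      synthetic_reference)
from phagemap.antigen import ANTIGEN_LOCAL, FUSION, ResidueSpan
from phagemap.simulate import SimConfig, simulate_library, simulate_selection

ref = synthetic_reference(seed=0)
epitope = [ResidueSpan(140, 154, ANTIGEN_LOCAL), ResidueSpan(248, 254, ANTIGEN_LOCAL)]
cfg = SimConfig(ref=ref, n_clones=50_000, empty_fraction=0.0,
                epitope_required_sets=epitope, w_binder=100.0,
                n_rounds=2, reads_per_round=20_000, seed=3)

lib_reads, truth = simulate_library(cfg)
sel_reads, _ = simulate_selection(truth, cfg)
print(f"library: {cfg.n_clones} clones, {truth.n_binders} true binders")

frags_u, _ = classify_library(lib_reads, ref, vector_flanks=cfg.flanks)
frags_s, sum_s = classify_library(sel_reads, ref, vector_flanks=cfg.flanks)
unsel = LibraryCounts.from_fragments(frags_u, "unselected")
sel = LibraryCounts.from_fragments(frags_s, "selected")
print(f"natural-frame reads: {unsel.total_natural_reads} unselected, "
      f"{sel.total_natural_reads} selected "
      f"({sum_s.fraction_natural:.2f} of selected insert reads)")

print("\ntop 3 enriched fragments (fusion coordinates):")
for call in rank_fragments(sel, top_n=3, unsel=unsel):
    print(f"  {call.span.label(ref.protein):>12}  "
          f"freq_sel {call.frequency_selected:.3f}  "
          f"freq_unsel {call.frequency_unselected:.5f}  "
          f"significant {call.significant}")
n_sig = sum(1 for c in call_significant(sel, unsel) if c.significant)
print(f"significant fragments (mean + 5 SD rule): {n_sig}")

profile = enrichment_factor(sel, unsel, ref)
sets_fusion = [convert_span(s, FUSION, ref) for s in epitope]
print(f"\nplanted required sets (fusion): "
      f"{[(s.start_res, s.end_res) for s in sets_fusion]}")
for call in call_hotspots(profile):
    region = candidate_required_region(call, profile)
    print(f"  boundary {call.boundary} ({call.direction}, z {call.jump_score:.1f})"
          f" -> candidate region {region.start_res}-{region.end_res}")
print("\nSelection concentrates the library on binder clones covering both")
print("stretches; the EF rise marks where binder coverage begins (bounded by")
print("the minimal fragment start compatible with covering both sets).")
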