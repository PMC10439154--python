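"""Screen lagged ASV features for downstream prediction, then read the
redundancy structure of the retained models as networks.

Each screening run permutes the candidate order, samples boosted-model
hyperparameters, and greedily accepts (window, lag) features of candidate
ASVs that strictly improve held-out accuracy on a downstream holdout (the
most downstream 15% of stations). Models that classify the held-out block
perfectly are retained; ASVs that never share a retained model are read
as informationally redundant (co-exclusion), ASVs that repeatedly appear
together as complementary (co-occurrence).

Runs at a reduced scale (30 stations, 12 ensemble runs) so the whole
script takes well under a minute; raise n_runs for a production ensemble.
"""

from riverindic import (
    RiverDesign,
    ScreenConfig,
    build_coexclusion,
    build_cooccurrence,
    ensemble_screen,
    minimal_models,
    presence_absence,
    select_best_models,
    simulate_dataset,
    taxonomy_dendrogram,
)

dataset = simulate_dataset(RiverDesign(n_stations=30), n_noise_taxa=40,
                           library_size=20_000, seed=11)
candidates = ["ASV_ind_a1", "ASV_ind_a2", "ASV_ind_b1", "ASV_ind_b2"]

ensemble = ensemble_screen(
    dataset, task="status", n_runs=12, seed=11, candidates=candidates,
    config=ScreenConfig(w_grid=(1,), l_grid=(0, 1, 2)),
)
best = select_best_models(ensemble)
print(f"retained {len(best)}/{len(ensemble)} models at 100% accuracy")

minimal, hubs = minimal_models(best)
print("smallest accepted sets:",
      sorted({tuple(sorted(m.asv_ids)) for m in minimal}))
if hubs:
    print("hub ASVs:", sorted(hubs))

pa = presence_absence(best)
co = build_cooccurrence(pa, percentile=0.0, taxonomy=dataset.taxonomy)
ex = build_coexclusion(pa, percentile=0.0)
print("co-occurrence edges:",
      sorted((u, v, d["weight"]) for u, v, d in co.edges(data=True)))
print("co-exclusion edges:", sorted(map(tuple, ex.edges())))

tree, freq = taxonomy_dendrogram(
    list(pa.columns), dataset.taxonomy, occurrences=pa.sum()
)
print("taxonomy dendrogram:", str(tree).strip())
print("occurrence frequencies:")
print(freq.round(3).to_string())
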