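"""Simulate a synthetic river survey and screen taxa by prevalence and CV.

The generator lays out three longitudinal transects (left bank, center,
right bank) along a shared river course, gives every station smooth
environmental gradients, and plants two redundancy groups of indicator
ASVs whose abundance switches between a low and a high regime at known
river-length fractions. A good snapshot bioindicator is present nearly
everywhere (high prevalence) yet strongly variable (high coefficient of
variation); this script ranks phyla and genera by exactly that rule.
"""

from riverindic import screen_rank, simulate_dataset, write_dataset

dataset = simulate_dataset(seed=7)
print(f"samples: {dataset.abundance.shape[0]}, "
      f"taxa: {dataset.abundance.shape[1]}")
print(dataset.metadata[["transect", "distance_to_mouth", "chl_a",
                        "status_class"]].head(3))

# conventions: 6 candidates at phylum level, 15 at genus level
for rank, n_top in (("Phylum", 6), ("Genus", 15)):
    screens = screen_rank(dataset, rank=rank, n_top=n_top)
    hits = screens[screens["candidate"]]
    print(f"\ntop {rank} candidates (prevalence / cv):")
    print(hits[["prevalence", "cv", "score"]].round(3).head(6))

paths = write_dataset(dataset, "scratch/example_dataset")
print("\nwrote:", ", ".join(str(p) for p in paths.values()))
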