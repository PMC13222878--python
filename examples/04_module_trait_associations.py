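"""Associate network modules with soil/root traits and classify shifts.

The untreated arm couples trait TOC to planted module 1; the treated arm
additionally couples NN to module 2. The analysis should keep the TOC
association ("maintained") and discover the NN one ("new").
"""

import pandas as pd
from scipy.spatial.distance import pdist, squareform

from rhizonet import (
    associate,
    build_network,
    classify_shift,
    correlation_screen,
    detect_modules,
    generate_community,
    generate_traits,
    mantel,
    module_profiles,
)

matrices = {}
for arm, links, seed in (("untreated", [1, 0], 1), ("biochar", [1, 2], 2)):
    table, truth = generate_community(n_samples=50, n_taxa=40, coupling=2.0,
                                      seed=seed)
    traits = generate_traits(truth, links, effect=2.0, noise_sd=0.5,
                             seed=seed + 10, trait_names=["TOC", "NN"])
    rho, p, _ = correlation_screen(table)
    part = detect_modules(build_network(rho, p, edge_alpha=0.01), seed=0)

    # align detected modules to the planted ids so the two arms share labels
    cols = {}
    for planted in (1, 2):
        best = max(part.top(part.n_modules),
                   key=lambda m: sum(truth.module_of.get(t) == planted
                                     for t in part.members(m)))
        cols[f"M{planted}"] = module_profiles(table, part, [best]).iloc[:, 0]
    profiles = pd.DataFrame(cols)
    trait_df = traits.values.set_axis(table.counts.index)
    matrices[arm] = associate(profiles, trait_df, alpha=0.01)

    r, pv = mantel(squareform(pdist(profiles.to_numpy())),
                   squareform(pdist(trait_df.to_numpy())), n_perm=999, seed=0)
    n_sig = int(matrices[arm].significant.to_numpy().sum())
    print(f"{arm:>9}: {n_sig} significant module-trait pairs at p < 0.01; "
          f"Mantel r = {r:.3f} (p = {pv:.4f})")

shift = classify_shift(matrices["untreated"], matrices["biochar"])
print(f"shift: new = {sorted(shift.new)}, maintained = {sorted(shift.maintained)}, "
      f"missed = {sorted(shift.missed)}")
print("A 'new' pair is significant only under the amendment - here the "
      "planted treated-only NN coupling, recovered by the full analysis chain.")
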