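"""Greedy feature-chain selection: which parameters carry the signal?

Reproduces the parameter-filtering procedure on a synthetic corpus: every
candidate parameter seeds a chain, the beam of best chains grows one
parameter per round, and the accuracy-versus-length curve identifies how
many parameters are worth keeping.  On synthetic data a handful of
placement-geometry parameters (top-stem size, overhang, contents) usually
saturate the curve quickly.
"""

import numpy as np

from mirsweep import default_catalog, eligible_names, greedy_parameter_selection
from mirsweep.simulate import HairpinRecipe, make_labeled_corpus
from mirsweep.structure import get_backend
from mirsweep.training import dataset_to_xy

backend = get_backend("vienna")
names = eligible_names(default_catalog())

dataset, _ = make_labeled_corpus(HairpinRecipe(), n_pos=90, level=1,
                                 rng=np.random.default_rng(3), backend=backend)
X, y = dataset_to_xy(dataset, names)
pos = X[y == 1].reset_index(drop=True)
neg = X[y == -1].reset_index(drop=True)

pool = [n for n in names
        if n.startswith(("mi_", "pre_", "upperstem_", "topstem_"))
        and not n.startswith("mi_firstbase")][:14]
thirds = lambda d: [d.iloc[i::3].reset_index(drop=True) for i in range(3)]
result = greedy_parameter_selection(thirds(pos[pool]), thirds(neg[pool]),
                                    beam=5, max_len=8, cv_folds=3)

print("chain length -> best mean CV accuracy")
for length, acc in result.curve:
    marker = "  <- best" if length == len(result.best_chain) else ""
    print(f"  {length:2d}   {acc:.3f}{marker}")
print(f"\nselected chain ({len(result.best_chain)} parameters):")
for p in result.best_chain:
    print(f"  {p}")
print("\nAccuracy typically plateaus after a few parameters; longer chains "
      "add noise rather than signal, which is why a filtered subset beats "
      "the full catalog.")
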