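"""Step through the binary assimilation operator on a 10-gene toy case.

An imperialist selecting {f1, f2, f5, f7, f10} assimilates a colony
selecting {f1, f3, f6, f8, f9, f10}: difference genes transfer with
learning rate beta, and a random template decides which of the colony's
own genes survive.
"""

import numpy as np

from hicats import (
    Country, apply_assimilation, difference_mask, selected_indices, transfer_count,
)

im = Country(np.array([1, 1, 0, 0, 1, 0, 1, 0, 0, 1]))
co = Country(np.array([1, 0, 1, 0, 0, 1, 0, 1, 1, 1]))
print("imperialist genes:", selected_indices(im))
print("colony genes:     ", selected_indices(co))

diff = difference_mask(im, co)
print("difference mask:  ", diff.tolist(), "->", int(diff.sum()), "difference genes")

beta = 0.6
k = transfer_count(int(diff.sum()), beta)
print(f"beta = {beta}: transfer {k} of the difference genes")

# pin the random draws: transfer f2 and f7; colony template keeps
# genes 2, 5 and 6 of its six selected genes (f3, f9, f10)
cobt = np.array([0, 1, 0, 0, 1, 1], dtype=np.uint8)
out = apply_assimilation(co, np.array([1, 6]), cobt)
print("assimilated colony:", selected_indices(out))
# the colony acquired two imperialist genes and dropped half of its own,
# so subsets shrink while drifting toward the empire's best solution
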