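"""Generate a rater-assignment grid at the full study scale.

55 items are dealt into 37 rater lists of six items each, so that every
item is annotated by at least four raters; each list crosses its items
with all 16 films (96 tasks per rater, blocked by item).
"""

import affectconsensus as ac

items = [f"item{k:02d}" for k in range(55)]
films = [f"film{k:02d}" for k in range(16)]
grid = ac.build_assignment_grid(items, films, n_lists=37, items_per_list=6, seed=0)

coverage = grid.coverage()
first = next(iter(grid.lists))
print(f"lists: {len(grid.lists)}, tasks per list: {len(grid.tasks(first))}")
print(f"items with 4 raters: {sum(1 for c in coverage.values() if c == 4)}")
print(f"items with 5 raters: {sum(1 for c in coverage.values() if c == 5)}")
print(f"example tasks for {first}: {grid.tasks(first)[:3]} ...")

# 37 lists x 6 slots = 222 exceeds 55 items x 4 raters = 220, so exactly two
# items receive a fifth rater -- these are the combos later subject to the
# worst-of-five exclusion.
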