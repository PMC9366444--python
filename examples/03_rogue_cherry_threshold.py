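"""When is a rogue *clade* worth keeping?

A cherry (X,Y) sits sister to leaf 1 in a fraction p1 of trees and sister
to leaf 6 otherwise, on a balanced rooted 6-leaf base.  Keeping the cherry
preserves the (certain) information that X and Y are sisters but drags
down supports elsewhere; dropping it yields a unanimous 6-leaf tree.  The
SPIC criterion prefers the plenary consensus only once one attachment is
frequent enough — the crossover sits just below 58.6% under rooted
(clade-count) scoring.
"""

from roguefinder import (figure2_fixture, figure2c_crossover,
                         majority_consensus, spic)

base = {"1", "2", "3", "4", "5", "6"}
print(" p1    plenary   reduced   preferred")
for pct in (52, 55, 58, 59, 62):
    trees = figure2_fixture("c", p1=pct / 100, n_trees=1000)
    plen = spic(majority_consensus(trees, rooted=True))
    red = spic(majority_consensus(trees, keep=base, rooted=True))
    print(f" {pct:2d}%   {plen:7.3f}   {red:7.3f}   "
          f"{'plenary' if plen > red else 'reduced'}")

rooted = figure2c_crossover(n_trees=1000, rooted=True)
unrooted = figure2c_crossover(n_trees=1000, rooted=False)
print(f"\ncrossover (rooted clade scoring):   {rooted:.2f}%")
print(f"crossover (unrooted split scoring): {unrooted:.2f}%")
print("\nAbove the crossover the rogue clade's certain monophyly outweighs "
      "the\nsupport it costs the rest of the tree; below it, drop the cherry.")
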