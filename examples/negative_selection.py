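"""Selecting reliable negative pairs with the transitive-closure heuristic.

In a (nearly) tree-shaped regulatory network, a pair of genes joined
only by a longer directed path, or by a reversed edge, is unlikely to be
a regulation itself.  The candidate negatives are therefore
(TC(P) ∪ Transpose(TC(P))) \\ P for the known network P, optionally
extended with a few random unlabeled pairs.
"""

from pugrn import GeneNetwork, pseudo_random_negatives, transitive_closure, transpose

known = GeneNetwork.from_edges({("a", "b"), ("b", "c")}, genes=("a", "b", "c", "d"))
print("known regulations:", sorted(known.edges))
print("transitive closure:", sorted(transitive_closure(known).edges))
print("transpose of closure:", sorted(transpose(transitive_closure(known)).edges))

negatives = pseudo_random_negatives(known, known.genes, random_fraction=0.0)
print("heuristic candidate negatives:", sorted(negatives))

extended = pseudo_random_negatives(known, known.genes, random_fraction=0.5, seed=1)
print(f"with a 50% random extension ({len(extended) - len(negatives)} extra pairs):",
      sorted(extended - negatives))
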