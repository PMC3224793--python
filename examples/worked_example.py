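"""The five-term demonstration ontology and the cosine function similarity.

Builds the small DAG in which term 4 has parents {term 2, term 3} and
term 5 has parents {term 3, term 4}, prints the binary ancestor vectors
of the two terms (direct-parents closure), and their cosine similarity.
"""

from ppigo import function_similarity, toy_ontology

onto = toy_ontology()
f, f_prime = "GO:0000004", "GO:0000005"

v = onto.term_vector(f, closure_mode="parents_only")
v_prime = onto.term_vector(f_prime, closure_mode="parents_only")

print(f"vector of {f}      : {tuple(v.dense())}")
print(f"vector of {f_prime}      : {tuple(v_prime.dense())}")
print(f"dot product            : {len(v.positions & v_prime.positions)}")
print(f"fsim(f, f')            : {function_similarity(v, v_prime):.12f}")
print()
print("The two functions annotate sibling branches of the DAG: they share")
print("two of three ancestor positions each, so the cosine of their binary")
print("ancestor vectors is 2/sqrt(3*3) = 2/3 — a graded similarity where an")
print("exact-match comparison would simply report 'different'.")
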