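"""Convolution tree kernel: fragment counting, SPT and dependency-path trees."""

from ddikernels import tree_kernel as tk

t = tk.parse_penn("(NP (DT the) (NN drug))")
print("tree:", t.to_penn())
print("K(T,T) at lambda=1 =", tk.cd_kernel(t, t, 1.0),
      " (the 6 common subtree fragments of the tree with itself)")
print("K(T,T) at lambda=0.4 =", round(tk.cd_kernel(t, t, 0.4), 4),
      " (each production discounted by the decay factor)")

sentence = tk.parse_penn(
    "(S (NP (NN DRUGA)) (VP (VBZ inhibits) (NP (NP (DT the) (NN metabolism))"
    " (PP (IN of) (NP (NN DRUGB))))) (. .))")
spt = tk.extract_spt(sentence, 0, 5)
print("\nSPT between the entity leaves:", spt.to_penn())

tokens = ["drug1", "interacts", "with", "drug2"]
deps = [(1, 0, "nsubj"), (1, 2, "prep"), (2, 3, "pobj")]
dpt = tk.dep_path_tree(deps, 0, 3, tokens)
print("dependency path tree:", dpt.to_penn())
print("\nThe SPT drops material outside the entity span; the flat path tree"
      "\nre-encodes the drug1->drug2 dependency path so the same fragment-"
      "\ncounting kernel can match path subsequences.")
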