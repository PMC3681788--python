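"""Feature-based kernel on the worked-example sentence.

Builds the blinded candidate pair "Plasma concentrations of drug1 are
decreased when administered with drug2 containing drug0 or drug0." and
prints the feature families the sparse kernel extracts from it.
"""

from ddikernels import feature_kernel as fk
from ddikernels.fixtures import golden_instance

inst = golden_instance()
print("sentence:", " ".join(inst.tokens))
print(f"d1={inst.d1} d2={inst.d2} END={inst.end}")

areas = fk.split_areas(inst)
print("left area:  ", fk.AreaSpans.tokens(inst, areas.left))
print("inner area: ", fk.AreaSpans.tokens(inst, areas.inner))
print("right area: ", fk.AreaSpans.tokens(inst, areas.right))
inner_count = inst.d2 - inst.d1 - 1
print(f"discretized distance for {inner_count} inner tokens:",
      fk.discretize_distance(inner_count))

vec = fk.assemble_vector(inst)
print(f"\nassembled vector has {len(vec)} features; a sample:")
for name in ("left_area=Plasma concentrations of",
             "D1_right=are",
             "D1_left^D2_left^distance=Plasma^are^5",
             "keyword=decrease", "nameisdrug_entity1",
             "semtype1=carb,phsu", "negative_word"):
    print(f"  {name} = {vec[name]:g}")

print("\nBinary n-gram and lexicon features fire on the areas around the two"
      "\nblinded drugs; NameIsDrug is -1 because both mentions are specific"
      "\ndrug names, and the inner-area verb 'decreased' matched the keyword"
      "\nlexicon entry 'decrease'.")
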