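"""Derive an L-system and embed leaf sub-grammars into the plant string.

Prints the classic algae derivation (whose string lengths follow the
Fibonacci numbers) and the organ spans of the bundled rosette preset: one
span per leaf instance, ready for per-organ mesh decomposition.
"""

from leafgen import derive, expand_hierarchical, load_grammar, parse_grammar, preset_path

algae = parse_grammar("axiom: A\nA -> A B\nB -> A")
print("algae derivations (lengths 1, 2, 3, 5, 8, ... — Fibonacci):")
for n in range(6):
    s = derive(algae, n)
    print(f"  n={n}: {s.plain()}  (length {len(s)})")

rosette = load_grammar(preset_path("rosette"))
string = expand_hierarchical(rosette, 10, seed=42)
print(f"\nrosette preset: {len(string.organ_spans)} leaf spans "
      f"in a {len(string)}-symbol string")
for span in string.organ_spans[:3]:
    print(f"  instance {span.instance_id} ({span.organ_class}): "
          f"symbols [{span.start}, {span.end})")
print("  ...")
print("Each span delimits one leaf's symbols; the turtle interpreter turns "
      "it into that leaf's own mesh.")
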