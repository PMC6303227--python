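"""Split-unit randomisation for the conveyor greenhouse.

Lines go to main units by a 7 x 6 Youden square (rows complete, columns
a balanced incomplete block design with concurrence lambda = 5); the
four salt treatments split into two lane-blocks of two per main unit by
a resolved incomplete block design balanced over the experiment.
"""

from saltphenome import assemble_layout, resolved_pair_blocks, youden_square
from saltphenome.design import block_concurrence_counts, concurrence_counts

square = youden_square(seed=2024)
print("7 x 6 Youden square (rows = replicates, columns = main positions):")
print(square.to_string())

counts = concurrence_counts(square)
print(f"\nAll {len(counts)} line pairs co-occur in "
      f"{sorted(set(counts.values()))} columns (lambda = 5: balanced).")

blocks = resolved_pair_blocks(seed=2024)
bcounts = block_concurrence_counts(blocks)
print(f"Treatment pairs share a lane-block {sorted(set(bcounts.values()))}"
      f" times each over 42 main units (84 blocks / 6 pairs = 14: balanced).")

layout = assemble_layout(square, blocks)
print(f"\nAssembled layout: {len(layout)} carts on lanes"
      f" {layout.lane.min()}-{layout.lane.max()}, positions"
      f" {[int(p) for p in sorted(layout.position.unique())[:4]]}... ;"
      f" every line x treatment"
      f" combination appears {layout.groupby(['line', 'treatment']).size().iloc[0]}"
      f" times (once per replicate).")
print(layout.head(8).to_string(index=False))
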