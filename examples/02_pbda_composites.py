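"""Poisson-blending data augmentation on a synthetic dataset.

Isolates single cells from paired images into a source pool, then pastes
randomly rescaled cells seamlessly onto a background, reporting the paste
log (accepted locations, scales) for one composite.
"""

from cellvstain import seeded_rng
from cellvstain.pbda import blank_background, build_source_pool, synthesize_composite
from cellvstain.synthdata import generate_scene, scene_to_pair

rng = seeded_rng(1)
pairs = [scene_to_pair(generate_scene(3, "round", (96, 96), rng=rng), 3,
                       pair_id=f"p{i}") for i in range(4)]
pool = build_source_pool(pairs, min_area=40)
print(f"source pool: {len(pool)} single cells isolated from {len(pairs)} pairs")

background = blank_background((96, 96), n_slices=3, rng=rng)
record = synthesize_composite(pool, background, max_cells=10,
                              scale_range=(0.8, 1.2), max_attempts=100, rng=rng)
print(f"composite: {record.n_accepted} cells pasted (max 10 attempted)")
for p in record.pastes:
    status = "ok " if p.accepted else "skip"
    print(f"  [{status}] instance {p.instance_index} at {p.location}, "
          f"scale {p.scale:.2f}")
print("Accepted masks never overlap; DIC, F-actin and nuclei channels share")
print("the same paste geometry, so the composite is a valid training pair.")
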