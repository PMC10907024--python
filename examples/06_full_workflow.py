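"""The complete workflow in one call: the tiny-preset demo recipe.

Synthesizes local + target datasets, runs PBDA, pretrains the ensemble,
matches the target dataset, few-shot fine-tunes U-Net and cGAN with 16
pairs, selects the combination ratio, evaluates, extracts features and
trains the YAP predictor.  Takes several minutes on one CPU.
"""

import json

from cellvstain.workbench import RunRecipe, run_recipe

summary = run_recipe(RunRecipe(seed=1, out_root="runs/full_demo"))

print("matched dataset:", summary["matching"]["matched_dataset"])
print("few-shot (n=16): fine-tuned median PCC",
      f"{summary['few_shot']['finetuned_median']:.3f} vs from-scratch",
      f"{summary['few_shot']['scratch_median']:.3f}")
print("combined-model test PCC:",
      json.dumps(summary["test_pcc"], indent=2))
print("morphometry agreement (min r over the 8 basic parameters):",
      summary["basic_feature_min_r"])
print("YAP held-out R^2 (median of 3):", summary["yap"]["holdout_r2_median"])
print("full summary written to runs/full_demo/summary.json")
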