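"""Full workflow: model grid, shortlist, and intelligent consensus.

Trains one SFS-MLR model per retained data division, ranks the models by
the average of MAE_LOO and MAE_test after an intercollinearity filter,
and combines the top three by the four consensus rules (plain average,
qualified average, error-weighted average, compound-wise best selection).
"""

from mixqspr.consensus import ConsensusConfig, consensus_predict
from mixqspr.features import compute_wm_features, drop_degenerate_columns
from mixqspr.simulate import SyntheticSpec, generate
from mixqspr.workflow import GridConfig, rank_and_select, run_grid

dataset, _ = generate(SyntheticSpec(rng_seed=5))
run = run_grid(dataset, grid_config=GridConfig(max_seed=2, max_interval=2))
cols = ["model_id", "strategy", "seed", "interval", "n_train", "n_test",
        "Q2_LOO", "Q2_LCO", "MAE_LOO", "R2_pred", "MAE_test"]
print(run.summary[cols].round(4).to_string(index=False))

shortlist = rank_and_select(run.summary, k=3)
print("\nshortlist (by mean of MAE_LOO and MAE_test, intercollinearity <= 0.80):")
print(shortlist[["model_id", "MAE_LOO", "MAE_test", "mae_mean"]]
      .round(5).to_string(index=False))

matrix = drop_degenerate_columns(compute_wm_features(dataset))
members = [run.models[m] for m in shortlist["model_id"]]
split = run.splits[shortlist["model_id"].iloc[0]]
train, test = matrix.subset(split.train_idx), matrix.subset(split.test_idx)
print("\nconsensus on the best model's test fold:")
for method in ("CM0", "CM1", "CM2", "CM3"):
    res = consensus_predict(ConsensusConfig(members, method=method), train, test)
    print(f"  {method}: MAE_test = {res.metrics['MAE_test']:.5f}  "
          f"R2_pred = {res.metrics.get('R2_pred', float('nan')):.4f}")
print("\nAll members recover the same planted model here, so the consensus")
print("rules coincide; with heterogeneous members CM1-CM3 can beat the")
print("plain average by down-weighting models outside their domain.")
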