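"""Enumerate mixtures-out and compounds-out train/test divisions.

Both strategies derive many deterministic divisions from a (seed,
interval) grid over the instance-count-sorted mixture or chemical lists;
the most-populated element always stays in training, and divisions with
less than 20% of records in the test set are discarded.
"""

from mixqspr.simulate import SyntheticSpec, generate
from mixqspr.splitting import describe_split, enumerate_co_splits, enumerate_mo_splits

dataset, _ = generate(SyntheticSpec(n_comp1=5, n_comp2=4, rng_seed=0))
print(f"dataset: {len(dataset)} records")

for name, splits in (
    ("mixtures-out", enumerate_mo_splits(dataset, max_seed=2, max_interval=2)),
    ("compounds-out", enumerate_co_splits(dataset, max_seed=2, max_interval=2)),
):
    print(f"\n{name}: {len(splits)} retained divisions")
    sp = min(splits, key=lambda s: s.test_fraction)  # most balanced one
    info = describe_split(sp, dataset)
    print(f"  most balanced division (seed={sp.seed}, interval={sp.interval}):")
    print(f"    train: {info['train']}")
    print(f"    test:  {info['test']}")
    print(f"    test fraction {sp.test_fraction:.2f}; "
          f"chemicals only in test: {info['chemicals_only_in_test']}")

print("\nA mixtures-out division keeps every unique mixture wholly on one")
print("side; a compounds-out division sends every record containing a")
print("selected chemical to the test side, so those chemicals are fully")
print("unseen during training.")
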