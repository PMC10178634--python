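"""Reproduce the class-balancing bookkeeping of three mammography datasets.

Starting from the published per-class image counts, the planner enumerates
flip/flip/rotate operation chains until each class reaches its exact
target, and the dataset totals come out at 12,000 / 8,000 / 12,000 with
50:50 train/test splits per class.
"""

from mammocad import ClassInventory, dataset_totals, plan_augmentation, split_train_test

datasets = {
    "CBIS-DDSM": [("benign", 557, 6000), ("malignant", 637, 6000)],
    "INbreast": [("benign", 76, 4000), ("malignant", 70, 4000)],
    "MIAS": [("benign", 52, 4000), ("malignant", 39, 4000), ("normal", 209, 4000)],
}

for name, rows in datasets.items():
    inventories = [ClassInventory(*row) for row in rows]
    for inv in inventories:
        plan = plan_augmentation(inv, seed=0)
        train, test = split_train_test(range(inv.target), ratio=0.5, seed=0)
        print(f"{name:9s} {inv.name:9s} {inv.initial_count:4d} -> {inv.target} "
              f"(+{len(plan)} generated), split {len(train)}/{len(test)}")
    print(f"{name:9s} total after augmentation: {dataset_totals(inventories)}")
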