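"""Score predictions and attribute correctness across the components.

Binary gate metrics follow the usual definitions (recall and
sensitivity are the same quantity); the Venn attribution partitions
the test set by which of the three component methods voted the gate
label correctly, showing what each contributes beyond the others.
"""

from rospred import (
    ConfusionCounts,
    binary_metrics,
    unique_correct_attribution,
)
from rospred.evaluation import format_metrics_table

m = binary_metrics(ConfusionCounts(tp=3, fn=1, fp=2, tn=4))
print("worked confusion table (tp=3, fn=1, fp=2, tn=4):")
print(format_metrics_table(m))

cnn_correct = {"s1", "s2", "s3", "s5"}
ffnn_correct = {"s2", "s3", "s4"}
gbt_correct = {"s3", "s4", "s5"}
universe = {f"s{i}" for i in range(1, 7)}
v = unique_correct_attribution(cnn_correct, ffnn_correct, gbt_correct, universe)
print("\ncorrectness Venn over", len(universe), "sequences:")
for region, count in v.as_dict().items():
    print(f"  {region}: {count}")
print("regions sum to the universe:", v.total == len(universe))
# 'only_*' counts are sequences a single method uniquely classifies
# correctly — the complementarity that motivates voting them together.
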