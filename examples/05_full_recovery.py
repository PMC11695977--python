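"""End-to-end parameter recovery at the default study conditions.

Runs every stage on the full-size planted dataset (3 x 12 Mb genome,
300 genes, 5 guides x 40 distal targets, 100k chimeric reads) and prints
how much of the planted structure the pipeline recovers.  Takes about a
minute.
"""

import json

from triadmap.pipeline import run_all
from triadmap.synthetic import SyntheticConfig

result = run_all(SyntheticConfig(seed=42))
print(json.dumps(result.summary, indent=1, default=float))
print()
print("guide candidate ranks:", result.guide_ranks)
print("per-knockdown target recall:", result.target_recall)
# recalls near 1 and guides occupying ranks 1..5 mean every stage of the
# chain preserved the planted lncRNA -> enhancer -> gene signal
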