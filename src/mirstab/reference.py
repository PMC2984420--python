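"""Published reference summary statistics bundled with the package.

``reference_group_summaries()`` loads the per-set summary statistics
(n, mean, sample sd) of the human, mouse and chicken pre-miRNA study
populations (miRBase release 14; S_n and S_c1-3 conservation sets) for
AMFE, base-pairing and nucleotide-composition metrics.  The chicken S_c1
set is absent: it fell below the five-member minimum and was excluded
from that study population.

These cells feed the summary-level aggregation helpers
(:func:`mirstab.stats.pooled_weighted_mean`, :func:`mirstab.stats.sd_ratio`,
:func:`mirstab.stats.mean_difference`), which treat published tables and
internally computed summaries identically.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def reference_group_summaries() -> pd.DataFrame:
    """DataFrame with columns species, group, metric, n, mean, sd."""
    ref = resources.files("mirstab.data") / "reference_group_summaries.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    expected = {"species", "group", "metric", "n", "mean", "sd"}
    missing = expected - set(df.columns)
    if missing:  # pragma: no cover - packaging defect
        raise RuntimeError(f"reference table is missing columns {sorted(missing)}")
    return df
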