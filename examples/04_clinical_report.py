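"""Recompute the clinical summary statistics from the bundled study table.

The bundled CSV carries the printed outcomes of a two-arm femoral
nerve-block study (25 patients per arm): nursing outcome counts,
complication counts, and block-duration summaries. Rates are recomputed
from the counts, group differences tested with Pearson's chi-square
(counts) and the pooled two-sample t test (mean ± SD summaries).
"""

import echodeblur as ed

experimental, control = ed.load_group_table()
table = ed.compare_groups(experimental, control)
print(table.to_string(index=False))
print("\nFlagged rows: the printed counts do not reach p < 0.05 under a "
      "chi-square test, although the block-duration differences are "
      "decisively significant.")
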