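#!/usr/bin/env python
"""Tallies and Venn partition of the packaged 70-compound marker table.

Every count is recomputed from the row-level table at run time; the
output is written to results/analysis/reference_tallies.json.
"""

import json
from pathlib import Path

from tomarker.reference import reference_summary

OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = reference_summary()
    (OUT / "reference_tallies.json").write_text(
        json.dumps(summary, indent=2, default=int)
    )
    print(f"{summary['n_compounds']} curated neuroactive compounds")
    print(f"  confidence levels: {summary['levels']}")
    print(f"  neuroactivity: {summary['neuroactivity']}")
    print(f"  protective classes: {summary['protective_classes']}")
    print(f"  discriminant per contrast: {summary['discriminant_sizes']}")
    print(f"  exclusive per contrast: {summary['exclusive_sizes']}")
    print(f"  full Venn partition: {summary['venn_regions']}")


if __name__ == "__main__":
    main()
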