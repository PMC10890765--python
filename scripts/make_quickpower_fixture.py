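"""Regenerate the packaged quickpower scenario tables from their recipes.

Run from the repository root:

    python scripts/make_quickpower_fixture.py
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from meripower.quickpower import SCENARIO_RECIPES, build_scenario  # noqa: E402

OUT = os.path.join(
    os.path.dirname(__file__), "..", "src", "meripower", "data", "quickpower"
)


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    for name in SCENARIO_RECIPES:
        result = build_scenario(name)
        tsv = os.path.join(OUT, f"{name}.tsv")
        result.table.to_csv(tsv, sep="\t", index=False)
        with open(os.path.join(OUT, f"{name}.meta.json"), "w") as fh:
            json.dump(result.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
        print(f"wrote {tsv} ({len(result.table)} rows)")


if __name__ == "__main__":
    main()
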