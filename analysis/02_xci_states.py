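"""Call per-cell XCI states across the simulated scenarios.

Expected pattern: the no-XCI and knockout populations are almost
entirely XaXa; graded random XCI spreads cells across XaXa -> XaXs/XsXa
-> XaXi/XiXa with the Xce skew favoring CAST-active (XiXa < XaXi is the
C57-preferential direction when skew < 0.5 silences maternal less often).
"""

from pathlib import Path

import pandas as pd

from xdosage import read_dataset
from xdosage.allelic import cell_states
from xdosage.io import write_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for ds in sorted((ROOT / "datasets").iterdir()):
        acm = read_dataset(ds)
        states = cell_states(acm)
        write_table(states, ROOT / f"xci_states_{ds.name}.tsv", ds.name)
        counts = states["xci_state"].value_counts().to_dict()
        rows.append({"scenario": ds.name, **counts})
        print(f"{ds.name}: {counts}")
    write_table(pd.DataFrame(rows).set_index("scenario").fillna(0).astype(int),
                ROOT / "xci_state_summary.tsv", "summary")


if __name__ == "__main__":
    main()
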