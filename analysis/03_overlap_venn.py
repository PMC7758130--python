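"""Direction-aware overlap of the two contexts' DE calls (the Venn step).

Genes overlap when DE in both contexts with concordant direction; miRNAs are
treated as overlapped when DE in both contexts regardless of direction.
"""

import pandas as pd
from _common import de_tables, load_all, parse_args

from mircrosstalk import diffexpr
from mircrosstalk.overlap import concordant_overlap


def main() -> None:
    args = parse_args(__doc__)
    bundle, _, _ = load_all(args.data)
    tables = de_tables(bundle)
    frames = []
    for assay in ("mrna", "mirna"):
        res = concordant_overlap(
            diffexpr.de_features(tables[assay]["ctx1"]),
            diffexpr.de_features(tables[assay]["ctx2"]),
        )
        summary = res.summary()
        summary.insert(0, "assay", assay)
        frames.append(summary)
        if assay == "mrna":
            print(f"genes: {len(res.concordant)} concordant overlap "
                  f"({len(res.shared_up)} up, {len(res.shared_down)} down), "
                  f"{len(res.discordant)} discordant")
        else:
            print(f"miRNAs DE in both contexts: {sorted(res.de_both)}")
    args.out.mkdir(parents=True, exist_ok=True)
    path = args.out / "venn_summary.tsv"
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    print(f"summary -> {path}")


if __name__ == "__main__":
    main()
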