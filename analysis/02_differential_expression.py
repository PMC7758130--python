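"""Moderated differential expression for both contrasts (B vs A, D vs C).

Fits the empirical-Bayes moderated t per assay and context and writes the
published-style DE tables (logFC, AveExpr, t, P, adjP, B, regulation) sorted
by ascending P.
"""

from _common import de_tables, load_all, parse_args

from mircrosstalk import diffexpr


def main() -> None:
    args = parse_args(__doc__)
    bundle, _, _ = load_all(args.data)
    tables = de_tables(bundle)
    args.out.mkdir(parents=True, exist_ok=True)
    for assay, label in (("mrna", ""), ("mirna", "mirna_")):
        for ctx in ("ctx1", "ctx2"):
            tab = tables[assay][ctx]
            path = args.out / f"de_{label}{ctx}.tsv"
            diffexpr.report_table(tab).to_csv(path, sep="\t", index=False,
                                              float_format="%.6g")
            called = diffexpr.de_features(tab)
            ups = sum(d == "up" for d in called.values())
            print(f"{assay} {ctx}: {len(called)} DE features "
                  f"({ups} up, {len(called) - ups} down) -> {path}")


if __name__ == "__main__":
    main()
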