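"""Hypergeometric over-representation of the overlapping DEGs in the pathway
and biological-process collections."""

from _common import de_tables, load_all, parse_args

from mircrosstalk import diffexpr, enrich
from mircrosstalk.overlap import concordant_overlap


def main() -> None:
    args = parse_args(__doc__)
    bundle, _, ann = load_all(args.data)
    tables = de_tables(bundle)
    overlap = concordant_overlap(
        diffexpr.de_features(tables["mrna"]["ctx1"]),
        diffexpr.de_features(tables["mrna"]["ctx2"]),
    )
    universe = list(bundle.mrna.matrix.index)
    args.out.mkdir(parents=True, exist_ok=True)
    for dim, collection in (("pathway", ann.pathways), ("bp", ann.bps)):
        res = enrich.ora(overlap.concordant, collection, universe)
        path = args.out / f"enrichment_{dim}.tsv"
        res.to_csv(path, sep="\t", index=False, float_format="%.6g")
        print(f"{dim}: {len(res)} terms tested, "
              f"{int(res['significant'].sum())} with p < 0.05 -> {path}")


if __name__ == "__main__":
    main()
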