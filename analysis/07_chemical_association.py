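"""Hypergeometric association of each DEmiRNA's target set with each
chemical's gene set; pairs with p < 0.05 become chemical-network edges."""

from _common import de_tables, load_all, parse_args

from mircrosstalk import nettopo, pipeline


def main() -> None:
    args = parse_args(__doc__)
    bundle, _, ann = load_all(args.data)
    tables = de_tables(bundle)
    merged = nettopo.merge_targets(ann.validated_targets, ann.predicted_targets)
    universe = list(bundle.mrna.matrix.index)
    screen = pipeline.stage_chemical_screen(tables, ann, merged, universe)
    retained = screen[screen["retained"]].drop(columns="retained")
    args.out.mkdir(parents=True, exist_ok=True)
    path = args.out / "chemical_edges.tsv"
    retained.to_csv(path, sep="\t", index=False, float_format="%.6g")
    print(f"{len(screen)} (miRNA, chemical) pairs tested, "
          f"{len(retained)} retained at p < 0.05 -> {path}")


if __name__ == "__main__":
    main()
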