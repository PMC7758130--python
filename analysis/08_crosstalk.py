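"""Meet/Min crosstalk scoring of cross-context miRNA pairs, network
construction, and identification of the bridging miRNAs."""

from _common import de_tables, load_all, parse_args

from mircrosstalk import nettopo, pipeline
from mircrosstalk.crosstalk import format_scores


def main() -> None:
    args = parse_args(__doc__)
    bundle, truth, ann = load_all(args.data)
    tables = de_tables(bundle)
    universe = list(bundle.mrna.matrix.index)
    nets = pipeline.stage_networks(tables, ann, top_k=30)
    drug_screen = pipeline.stage_drug_screen(tables, ann)
    chem_screen = pipeline.stage_chemical_screen(
        tables, ann, nets["merged_targets"], universe)
    collection = pipeline.build_feature_sets(
        tables, ann, nets, drug_screen, chem_screen, universe)
    rows, network, bridging = pipeline.stage_crosstalk(collection)

    args.out.mkdir(parents=True, exist_ok=True)
    format_scores(rows).to_csv(args.out / "crosstalk_scores.tsv", sep="\t",
                               index=False)
    with open(args.out / "crosstalk_network.sif", "w") as fh:
        for u, v in sorted(network.edges()):
            fh.write(f"{u}\tcrosstalk\t{v}\n")
    (args.out / "bridging_mirnas.txt").write_text(
        "".join(f"{m}\n" for m in bridging))

    print(f"{len(rows)} cross-context pairs scored, "
          f"{network.number_of_edges()} retained after filtering")
    print(f"bridging miRNAs: {bridging}")
    print(f"planted shared miRNAs: {sorted(truth.planted_shared_mirnas)}")
    match = sorted(bridging) == sorted(truth.planted_shared_mirnas)
    print("recovered planted crosstalk:", "yes" if match else "no")


if __name__ == "__main__":
    main()
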