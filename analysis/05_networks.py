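"""Assemble the PPI, TF-target and DEmiRNA-target networks per context and
rank nodes by NetworkAnalyzer-style topology metrics."""

from _common import de_tables, load_all, parse_args

from mircrosstalk import pipeline


def main() -> None:
    args = parse_args(__doc__)
    bundle, _, ann = load_all(args.data)
    tables = de_tables(bundle)
    nets = pipeline.stage_networks(tables, ann, top_k=30)
    args.out.mkdir(parents=True, exist_ok=True)
    for ctx, graphs in nets["graphs"].items():
        for name, g in graphs.items():
            tab = nets["tables"][ctx][name]
            path = args.out / f"{name}_{ctx}_metrics.tsv"
            tab.to_csv(path, sep="\t", index=False, float_format="%.6g")
            print(f"{name} {ctx}: {g.number_of_nodes()} nodes, "
                  f"{g.number_of_edges()} edges; top node "
                  f"{tab['node'].iloc[0] if len(tab) else '-'} -> {path}")


if __name__ == "__main__":
    main()
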