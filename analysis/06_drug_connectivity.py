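"""KS connectivity screen of the DEmiRNA tag sets against every drug's ranked
signature, with cross-context concordance labels."""

from _common import de_tables, load_all, parse_args

from mircrosstalk import pipeline


def main() -> None:
    args = parse_args(__doc__)
    bundle, _, ann = load_all(args.data)
    tables = de_tables(bundle)
    screen = pipeline.stage_drug_screen(tables, ann)
    args.out.mkdir(parents=True, exist_ok=True)
    path = args.out / "drug_screen.tsv"
    screen.to_csv(path, sep="\t", index=False, float_format="%.6g")
    counts = screen["concordance"].value_counts().to_dict() if len(screen) else {}
    print(f"{len(screen)} drugs screened in both contexts: {counts} -> {path}")


if __name__ == "__main__":
    main()
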