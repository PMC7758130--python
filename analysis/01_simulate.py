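"""Simulate the four-group coculture study (expression + annotations + truth).

Writes the synthetic dataset used by all later analysis steps to
results/data: two log2 expression matrices (mRNA, miRNA) over groups A-D,
the sample design, miRNA target tables, pathway/BP collections, PPI and TF
edges, chemical gene sets, per-drug ranked signatures, and the ground truth.
"""

from _common import parse_args

from mircrosstalk import synthdata


def main() -> None:
    args = parse_args(__doc__, need_data=False)
    cfg = synthdata.SynthConfig(seed=args.seed)
    bundle, truth = synthdata.generate_study(cfg)
    ann = synthdata.generate_annotations(cfg, truth)
    data_dir = args.out / "data"
    synthdata.write_study(bundle, truth, data_dir)
    synthdata.write_annotations(ann, data_dir)
    print(f"simulated {cfg.n_genes} genes x {bundle.mrna.matrix.shape[1]} samples"
          f" and {cfg.n_mirnas} miRNAs (seed {args.seed})")
    print(f"planted: {len(truth.planted_de_genes['ctx1'])}/"
          f"{len(truth.planted_de_genes['ctx2'])} DE genes per context, "
          f"{sorted(truth.planted_shared_mirnas)} shared DEmiRNAs")
    print(f"data written to {data_dir}")


if __name__ == "__main__":
    main()
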