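"""Assign every normalised CDS to an FBP enzyme family by relaxed local
similarity search against the seed queries (E <= 1e-50)."""

from common import parse_seed, pipeline_config

from annoconcord.annotation_io import Source
from annoconcord.pipeline import run_subcommand


def main() -> None:
    config = pipeline_config(parse_seed(__doc__))
    assignments = run_subcommand("mine", config)
    for source in (Source.SOURCE_A, Source.SOURCE_B):
        nested = assignments[source]
        total = sum(len(g) for by_sp in nested.values() for g in by_sp.values())
        print(f"source {source.value}: {total} homologs")
        for enz in sorted(nested, key=lambda e: e.value):
            n = sum(len(g) for g in nested[enz].values())
            print(f"  {enz.value:7s} {n:4d}")
    print(f"artifacts in {config.outdir}/mine/")


if __name__ == "__main__":
    main()
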