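"""Score the pipeline against the simulator's ground truth: what fraction of
emitted annotations received their implied category?"""

from pathlib import Path

from common import parse_seed, pipeline_config

from annoconcord.pairs import read_pair_table
from annoconcord.simulate import TruthTable, category_recovery


def main() -> None:
    config = pipeline_config(parse_seed(__doc__))
    outdir = Path(config.outdir)
    truth = TruthTable.read(outdir / "simulate" / "truth.tsv")
    records = read_pair_table(outdir / "rescue" / "pairs_rescued.tsv")
    fraction, matched, total = category_recovery(truth, records)
    print(f"category recovery: {matched}/{total} = {100 * fraction:.2f}%")
    rescued = sum(1 for r in records if r.rescued_by_tree)
    print(f"tree-rescued pairs: {rescued}")


if __name__ == "__main__":
    main()
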