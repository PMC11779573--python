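"""Plot survival by group and per-species reaction norms from the run's
replicate summaries (results/survival_by_group.png, results/reaction_norms.png)."""

from pathlib import Path

from countergrad.pipeline import summarize_figures

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    paths = summarize_figures({"config": {"output_dir": str(RESULTS)}}, output_dir=str(RESULTS))
    for p in paths:
        print("wrote", p)


if __name__ == "__main__":
    main()
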