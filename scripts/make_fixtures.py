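"""Regenerate the hand-computed 2x2 fixture CSV used by the test suite."""

from pathlib import Path

from nmasim.oracles import write_fixture_csv

if __name__ == "__main__":
    out = Path(__file__).resolve().parent.parent / "tests" / "data" / "fixture_tables.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    write_fixture_csv(out)
    print(f"wrote {out}")
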