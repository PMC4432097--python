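"""Regenerate the committed golden SVGs under tests/golden/.

Run from the repository root: python scripts/make_goldens.py
"""

import sys
import tempfile
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "tests"))

from _golden import GOLDEN_DIR, render_scenarios  # noqa: E402


def main() -> None:
    GOLDEN_DIR.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory() as tmp:
        rendered = render_scenarios(Path(tmp))
    for name, data in rendered.items():
        out = GOLDEN_DIR / f"{name}.svg"
        out.write_bytes(data)
        print(f"wrote {out} ({len(data)} bytes)")


if __name__ == "__main__":
    main()
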