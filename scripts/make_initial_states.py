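"""Regenerate the shipped condition initial states by pacing from the
bootstrap guess.  Usage: python scripts/make_initial_states.py [n_beats]"""
import json
import sys
from pathlib import Path

from atriomech.state import CONDITIONS, regenerate_initial_state

def main():
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 500
    out = {}
    for cond in CONDITIONS:
        state, meta = regenerate_initial_state(cond, bcl=1000.0, n_beats=n)
        out[cond] = {"state": [float(v) for v in state.values], **meta}
        print(cond, "beats:", meta["n_beats"], "converged:",
              meta["converged"], "Vm=%.2f" % state["Vm"])
    path = Path(__file__).resolve().parents[1] / "src" / "atriomech" / \
        "data" / "initial_states.json"
    path.write_text(json.dumps(out, indent=1))
    print("wrote", path)

if __name__ == "__main__":
    main()
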