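#!/usr/bin/env python
"""Materialize the artificial language and its training streams.

Writes the canonical language config, one sample training epoch per
encoding (the tab-separated cue/outcome event format), and the
pseudorandomized behavioral trial order, then prints the structural checks
a reader would want to see: 32 nouns in 4 classes, 103 presentations per
class and epoch, the deliberate class-2/4 form and class-3/4 meaning
ambiguities, and the uniphone round-trip.
"""

import argparse
from pathlib import Path

from marklearn.language import (
    behavioral_trial_order,
    build_language_spec,
    generate_events,
    uniphones_to_form,
    write_events,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/language"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    spec = build_language_spec()
    spec.to_yaml(out / "language.yaml")
    for marking, encoding in [("pre", "sim1"), ("post", "sim1"), ("pre", "sim2")]:
        events = generate_events(spec, marking, encoding, spec.trials_per_epoch, args.seed)
        write_events(events, out / f"events_{encoding}_{marking}.tsv")

    order = behavioral_trial_order(spec, args.seed)
    (out / "behavioral_order.tsv").write_text(
        "trial\tnoun\tclass\tfrequency\n"
        + "".join(
            f"{t}\t{n.form}\t{n.noun_class}\t{n.frequency}\n"
            for t, n in enumerate(order, 1)
        )
    )

    print(f"nouns: {len(spec.nouns)} in 4 classes, epoch = {spec.trials_per_epoch} trials")
    for k in (1, 2, 3, 4):
        cls = spec.nouns_of_class(k)
        print(
            f"  class {k}: premarker {spec.markers.premarkers[k]}, "
            f"postmarker {spec.markers.postmarkers[k]}, "
            f"meaning {sorted(spec.features.class_to_meaning_set[k])}, "
            f"form {sorted(spec.features.class_to_form_set[k])}, "
            f"frequency sum {sum(n.frequency for n in cls)}"
        )
    print(
        "shared sets: form(class2) == form(class4):",
        spec.features.class_to_form_set[2] == spec.features.class_to_form_set[4],
        "| meaning(class3) == meaning(class4):",
        spec.features.class_to_meaning_set[3] == spec.features.class_to_meaning_set[4],
    )
    ok = all(uniphones_to_form(spec.uniphones(n.form)) == n.form for n in spec.nouns)
    print(f"uniphone round-trip over the whole lexicon: {'ok' if ok else 'FAILED'}")
    print(f"oksham -> {' '.join(spec.uniphones('oksham'))}")
    print(f"first 112 behavioral trials all high-frequency: "
          f"{all(n.frequency >= 11 for n in order[:112])}")
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
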