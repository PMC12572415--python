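# Default reference-structurer configuration: certainty cue phrases,
# follow-up recommendation surfaces, and sentence delimiters.
# Cue patterns are full phrases matched within the (normalized) sentence;
# when several cues co-occur the most guarded label wins
# (denial > unlikely > may_represent > likely > definite).
certainty_cues:
  - {pattern: 認めません, label: denial}
  - {pattern: 認めない, label: denial}
  - {pattern: ありません, label: denial}
  - {pattern: なし, label: denial}
  - {pattern: 否定的, label: denial}
  - {pattern: no evidence of, label: denial}
  - {pattern: 可能性は低い, label: unlikely}
  - {pattern: 考えにくい, label: unlikely}
  - {pattern: unlikely, label: unlikely}
  - {pattern: 可能性があります, label: may_represent}
  - {pattern: 可能性がある, label: may_represent}
  - {pattern: かもしれません, label: may_represent}
  - {pattern: may represent, label: may_represent}
  - {pattern: 疑われます, label: likely}
  - {pattern: 疑います, label: likely}
  - {pattern: 疑う, label: likely}
  - {pattern: 疑い, label: likely}
  - {pattern: 示唆, label: likely}
  - {pattern: suggests, label: likely}
  - {pattern: suspected, label: likely}
  - {pattern: 認めます, label: definite}
  - {pattern: 認める, label: definite}
  - {pattern: みられます, label: definite}
follow_up_surfaces:
  - フォロー
  - 追加検査
  - 経過観察
  - 精査
  - follow-up
  - further evaluation
sentence_delimiters: "。．.!?！？\n"
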