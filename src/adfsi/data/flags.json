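{
  "T1": [
    {
      "row": "ACF at 6 L/min",
      "column": "LSA",
      "value": "16.651",
      "note": "Physically implausible outflow (exceeds the 6 L/min pump flow). Preserved verbatim. Hypotheses: decimal slip for 1.665 (row imbalance would become 0.035 L/min) or digit transposition; undetermined from the printed text alone.",
      "kind": "suspected_typo"
    },
    {
      "row": "ACF at 6 L/min",
      "column": "printed_label",
      "value": "ACF",
      "note": "Scenario label printed as 'ACF' instead of 'AFC'; normalized in the 'scenario' column, preserved in 'printed_label'.",
      "kind": "label_typo"
    },
    {
      "row": "all",
      "column": null,
      "value": null,
      "note": "Row mass balances of the printed values: AC 0.001/0.018/0.041/0.080/0.025 and AFC 0.012/0.009/0.025/15.009/0.015 L/min for 3-7 L/min. Only the flagged 6 L/min AFC row exceeds 0.05 L/min besides AC at 6 L/min (0.080).",
      "kind": "consistency_audit"
    },
    {
      "row": "derived",
      "column": null,
      "value": null,
      "note": "The running text quotes the visceral increase range as '96 to 132%' while the table arithmetic gives 132.85% at 7 L/min (133 when rounded half away from zero); the same text later uses '97 to 133%'. Rounding inconsistency in the source, not in the replicas.",
      "kind": "rounding_inconsistency"
    }
  ],
  "T2": [
    {
      "row": "all",
      "column": null,
      "value": null,
      "note": "Packaged for comparison only. The text's derived CA+SMA percent increases (67-125%) are not exactly reproducible from the printed mean values ((0.55+0.31)/(0.25+0.13)-1 = 126% at 3 L/min); no derived targets are computed from this table.",
      "kind": "comparison_only"
    },
    {
      "row": "ACF at 6 L/min",
      "column": "printed_label",
      "value": "ACF",
      "note": "Same 'ACF' label slip as Table 1.",
      "kind": "label_typo"
    }
  ],
  "T3": [],
  "T4": [],
  "T5": []
}
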