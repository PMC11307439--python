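{
  "response_name": "ct_vat",
  "constant": 249.0,
  "basis_functions": [
    {
      "coefficient": -79.9,
      "factors": [
        {"kind": "indicator", "variable": "sex", "level": "female"}
      ]
    },
    {
      "coefficient": -4.4,
      "factors": [
        {"kind": "hinge", "variable": "wc", "knot": 111.0, "direction": "below"}
      ]
    },
    {
      "coefficient": -5.14,
      "factors": [
        {"kind": "hinge", "variable": "hc", "knot": 106.0, "direction": "above"}
      ]
    },
    {
      "coefficient": -29.5,
      "factors": [
        {"kind": "hinge", "variable": "bmi", "knot": 25.9, "direction": "below"}
      ]
    },
    {
      "coefficient": 13.0,
      "factors": [
        {"kind": "hinge", "variable": "bmi", "knot": 25.9, "direction": "above"}
      ]
    },
    {
      "coefficient": 7.18,
      "factors": [
        {"kind": "indicator", "variable": "sex", "level": "female"},
        {"kind": "hinge", "variable": "bmi", "knot": 29.0, "direction": "below"}
      ]
    },
    {
      "coefficient": 0.459,
      "factors": [
        {"kind": "hinge", "variable": "wc", "knot": 111.0, "direction": "below"},
        {"kind": "hinge", "variable": "bmi", "knot": 28.4, "direction": "below"}
      ]
    }
  ]
}
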