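{
  "b2013_dep": "6ec64c8f700f35bff80df5cb6a4eca666a1fb2d087b173af2e290afc254f72bb",
  "b2013_pwb": "e12f3daa3dc02207b49acaef484f987b36d6d1c1a1915679e81bff775143b59f",
  "b2013_swb": "221a8b2fc1171124f056847907521d1a5fe9d10a4aa6968b97f435ad48955669",
  "sl2009_dep": "1f78c1bee6e85248f2dfe566a8a0fb1d39c0a9edc7f8cd7283190b2372253b0d",
  "sl2009_wb": "d40acc5e9d249a11e0edf07df22c051d08324aae669417ee753411a734aedd47"
}
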