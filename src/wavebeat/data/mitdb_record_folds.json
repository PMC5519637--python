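{
  "1": ["100", "101", "109", "118", "217"],
  "2": ["105", "106", "107", "111", "124"],
  "3": ["104", "112", "113", "114", "207"],
  "4": ["102", "116", "117", "212", "214"],
  "5": ["107", "109", "122", "123", "231"],
  "6": ["111", "202", "203", "217", "232"],
  "7": ["102", "118", "207", "209", "210"],
  "8": ["104", "124", "214", "215", "219"],
  "9": ["109", "207", "217", "222"],
  "10": ["102", "111", "212", "233"]
}
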