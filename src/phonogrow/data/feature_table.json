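{
 "version": "1",
 "parameters": {
  "c_skip": -10.0,
  "c_sub": 35.0,
  "c_exp": 45.0,
  "c_vwl": 10.0
 },
 "salience": {
  "syllabic": 5.0,
  "place": 40.0,
  "manner": 50.0,
  "voice": 10.0,
  "nasal": 10.0,
  "retroflex": 10.0,
  "lateral": 10.0,
  "aspirated": 5.0,
  "long": 1.0,
  "high": 5.0,
  "back": 5.0,
  "round": 5.0
 },
 "segments": {
  "p": {
   "type": "consonant",
   "place": "bilabial",
   "manner": "stop"
  },
  "b": {
   "type": "consonant",
   "place": "bilabial",
   "manner": "stop",
   "voice": 1
  },
  "t": {
   "type": "consonant",
   "place": "alveolar",
   "manner": "stop"
  },
  "d": {
   "type": "consonant",
   "place": "alveolar",
   "manner": "stop",
   "voice": 1
  },
  "k": {
   "type": "consonant",
   "place": "velar",
   "manner": "stop"
  },
  "g": {
   "type": "consonant",
   "place": "velar",
   "manner": "stop",
   "voice": 1
  },
  "m": {
   "type": "consonant",
   "place": "bilabial",
   "manner": "stop",
   "voice": 1,
   "nasal": 1
  },
  "n": {
   "type": "consonant",
   "place": "alveolar",
   "manner": "stop",
   "voice": 1,
   "nasal": 1
  },
  "ŋ": {
   "type": "consonant",
   "place": "velar",
   "manner": "stop",
   "voice": 1,
   "nasal": 1
  },
  "f": {
   "type": "consonant",
   "place": "labiodental",
   "manner": "fricative"
  },
  "v": {
   "type": "consonant",
   "place": "labiodental",
   "manner": "fricative",
   "voice": 1
  },
  "θ": {
   "type": "consonant",
   "place": "dental",
   "manner": "fricative"
  },
  "ð": {
   "type": "consonant",
   "place": "dental",
   "manner": "fricative",
   "voice": 1
  },
  "s": {
   "type": "consonant",
   "place": "alveolar",
   "manner": "fricative"
  },
  "z": {
   "type": "consonant",
   "place": "alveolar",
   "manner": "fricative",
   "voice": 1
  },
  "ʃ": {
   "type": "consonant",
   "place": "palato-alveolar",
   "manner": "fricative"
  },
  "ʒ": {
   "type": "consonant",
   "place": "palato-alveolar",
   "manner": "fricative",
   "voice": 1
  },
  "h": {
   "type": "consonant",
   "place": "glottal",
   "manner": "fricative"
  },
  "ʧ": {
   "type": "consonant",
   "place": "palato-alveolar",
   "manner": "affricate"
  },
  "ʤ": {
   "type": "consonant",
   "place": "palato-alveolar",
   "manner": "affricate",
   "voice": 1
  },
  "l": {
   "type": "consonant",
   "place": "alveolar",
   "manner": "approximant",
   "voice": 1,
   "lateral": 1
  },
  "r": {
   "type": "consonant",
   "place": "alveolar",
   "manner": "approximant",
   "voice": 1,
   "retroflex": 1
  },
  "w": {
   "type": "consonant",
   "place": "velar",
   "manner": "approximant",
   "voice": 1
  },
  "j": {
   "type": "consonant",
   "place": "palatal",
   "manner": "approximant",
   "voice": 1
  },
  "i": {
   "type": "vowel",
   "height": 1.0,
   "backness": "front",
   "long": 1
  },
  "ɪ": {
   "type": "vowel",
   "height": 0.9,
   "backness": "front"
  },
  "e": {
   "type": "vowel",
   "height": 0.6,
   "backness": "front"
  },
  "ɛ": {
   "type": "vowel",
   "height": 0.4,
   "backness": "front"
  },
  "æ": {
   "type": "vowel",
   "height": 0.15,
   "backness": "front"
  },
  "a": {
   "type": "vowel",
   "height": 0.0,
   "backness": "central"
  },
  "ɑ": {
   "type": "vowel",
   "height": 0.0,
   "backness": "back",
   "long": 1
  },
  "ʌ": {
   "type": "vowel",
   "height": 0.4,
   "backness": "back"
  },
  "ə": {
   "type": "vowel",
   "height": 0.5,
   "backness": "central"
  },
  "ɜ": {
   "type": "vowel",
   "height": 0.5,
   "backness": "central",
   "long": 1
  },
  "o": {
   "type": "vowel",
   "height": 0.6,
   "backness": "back",
   "round": 1,
   "long": 1
  },
  "ɔ": {
   "type": "vowel",
   "height": 0.35,
   "backness": "back",
   "round": 1
  },
  "u": {
   "type": "vowel",
   "height": 1.0,
   "backness": "back",
   "round": 1,
   "long": 1
  },
  "ʊ": {
   "type": "vowel",
   "height": 0.9,
   "backness": "back",
   "round": 1
  }
 }
}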