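[
 {
  "name": "RING-M",
  "priority": 0,
  "accessory": false,
  "slots": [
   {
    "allowed": "M",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "R",
    "spacer": [
     14,
     14
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     1,
     1
    ]
   },
   {
    "allowed": "H",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     10,
     10
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C"
   }
  ]
 },
 {
  "name": "RING-D",
  "priority": 1,
  "accessory": false,
  "slots": [
   {
    "allowed": "C",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     9,
     39
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     1,
     3
    ]
   },
   {
    "allowed": "H",
    "spacer": [
     2,
     3
    ]
   },
   {
    "allowed": "D",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     4,
     48
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C"
   }
  ]
 },
 {
  "name": "RING-H2",
  "priority": 2,
  "accessory": false,
  "slots": [
   {
    "allowed": "C",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     9,
     39
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     1,
     3
    ]
   },
   {
    "allowed": "H",
    "spacer": [
     2,
     3
    ]
   },
   {
    "allowed": "H",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     4,
     48
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C"
   }
  ]
 },
 {
  "name": "RING-HC",
  "priority": 3,
  "accessory": false,
  "slots": [
   {
    "allowed": "C",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     9,
     39
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     1,
     3
    ]
   },
   {
    "allowed": "H",
    "spacer": [
     2,
     3
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     4,
     48
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C"
   }
  ]
 },
 {
  "name": "IBR",
  "priority": 10,
  "accessory": true,
  "slots": [
   {
    "allowed": "C",
    "spacer": [
     4,
     4
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     14,
     30
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     1,
     4
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     4,
     4
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     2,
     2
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     4,
     4
    ]
   },
   {
    "allowed": "C",
    "spacer": [
     4,
     4
    ]
   },
   {
    "allowed": "H",
    "spacer": [
     4,
     4
    ]
   },
   {
    "allowed": "C"
   }
  ]
 }
]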