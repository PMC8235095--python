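{
 "transmitter": {
  "windings": 36,
  "radius_mm": 5.0,
  "current_a_rms": 1.0,
  "frequency_hz": 182000.0
 },
 "receivers": [
  {
   "position_mm": [
    -120.0,
    -120.0,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -120.0,
    -39.99999999999999,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -120.0,
    40.00000000000001,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -120.0,
    120.0,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -39.99999999999999,
    -120.0,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -39.99999999999999,
    -39.99999999999999,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -39.99999999999999,
    40.00000000000001,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -39.99999999999999,
    120.0,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    40.00000000000001,
    -120.0,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    40.00000000000001,
    -39.99999999999999,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    40.00000000000001,
    40.00000000000001,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    40.00000000000001,
    120.0,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    120.0,
    -120.0,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    120.0,
    -39.99999999999999,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    120.0,
    40.00000000000001,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    120.0,
    120.0,
    0.0
   ],
   "normal": [
    0.0,
    0.0,
    1.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -40.0,
    -150.0,
    109.99999999999999
   ],
   "normal": [
    0.0,
    1.0,
    0.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -40.0,
    -150.0,
    190.0
   ],
   "normal": [
    0.0,
    1.0,
    0.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    40.0,
    -150.0,
    109.99999999999999
   ],
   "normal": [
    0.0,
    1.0,
    0.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    40.0,
    -150.0,
    190.0
   ],
   "normal": [
    0.0,
    1.0,
    0.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -150.0,
    -40.0,
    109.99999999999999
   ],
   "normal": [
    1.0,
    0.0,
    0.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -150.0,
    -40.0,
    190.0
   ],
   "normal": [
    1.0,
    0.0,
    0.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -150.0,
    40.0,
    109.99999999999999
   ],
   "normal": [
    1.0,
    0.0,
    0.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  },
  {
   "position_mm": [
    -150.0,
    40.0,
    190.0
   ],
   "normal": [
    1.0,
    0.0,
    0.0
   ],
   "windings": 252,
   "radius_mm": 9.5
  }
 ]
}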