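# Weekly Sunday topic messages; rotate in order, wrapping when exhausted.
# Links are opaque strings to hosted educational videos.
topics:
  - title: "Dining out on DASH"
    link: "https://videos.example.org/dash/dining-out"
  - title: "Reading nutrition labels"
    link: "https://videos.example.org/dash/labels"
  - title: "DASH on a budget"
    link: "https://videos.example.org/dash/budget"
  - title: "Smart snacking with DASH"
    link: "https://videos.example.org/dash/snacking"
  - title: "Cooking at home the DASH way"
    link: "https://videos.example.org/dash/cooking"
  - title: "Cutting sodium without losing flavor"
    link: "https://videos.example.org/dash/sodium"
  - title: "Women's heart health and DASH"
    link: "https://videos.example.org/dash/heart-health"
  - title: "Staying on track when life gets busy"
    link: "https://videos.example.org/dash/staying-on-track"
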