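# Search-intent words removed from queries only (not from corpus text).
# User-overridable via StopwordConfig.
find
search
data
datasets
databases
related
types
mention
regarding
across
all
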