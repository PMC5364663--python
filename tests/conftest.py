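import numpy as np
import pytest

# 10-point eyes-closed resting-state excerpt used to illustrate the
# symbolization chain; its mean is 2.3404 and, with threshold offset 1.2 and
# word length 3, it produces the word series
# {(001),(011),(111),(110),(100),(000),(000),(000)} and code series
# {1,3,7,6,4,0,0,0}.
WORKED_SERIES = (0.5378, 2.0403, 5.1684, 7.8292, 7.3310,
                 3.4433, 0.4669, -0.3348, -0.7980, -2.2799)


@pytest.fixture
def worked_series() -> np.ndarray:
    return np.array(WORKED_SERIES)
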